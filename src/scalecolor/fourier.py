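"""2-D Fourier analysis of refractive-index maps and coherent-scattering
reflectance prediction.

Spatial periodicity in refractive index scatters light coherently:
a spatial-frequency component f (cycles/nm) of the index variation
back-scatters wavelength lambda = 2*n_bar/f at normal incidence, where
n_bar is the volume-weighted mean index of the tissue (the round-trip
optical path over one period). The predicted reflectance spectrum is
therefore the radially averaged Fourier power spectrum of the index
matrix, re-expressed on a wavelength axis; its peak lambda_max is the
predicted hue. With n_bar computed from the analyzed region's fill
fraction this mapping reproduces the ideal-multilayer peak
2*(n1*d1 + n2*d2) exactly for a two-phase periodic stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_prep import IndexMap

#: visible band used when restricting predicted peaks (nm)
VISIBLE_BAND = (350.0, 700.0)


@dataclass
class PowerSpectrum:
    power: np.ndarray  # squared magnitudes, zero-frequency centered
    freq_step: float  # cycles/nm per bin along each axis
    total_power: float
    dc_removed: bool
    n_bar: float

    def save_heatmap(self, path: str | Path) -> None:
        """Log-scaled heat map of the centered power spectrum."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = self.power.shape[0]
        extent_f = self.freq_step * n / 2
        fig, ax = plt.subplots(figsize=(5, 4.2))
        im = ax.imshow(np.log10(self.power + 1e-12), origin="lower",
                       extent=[-extent_f, extent_f, -extent_f, extent_f],
                       cmap="jet")
        ax.set_xlabel("spatial frequency (cycles/nm)")
        ax.set_ylabel("spatial frequency (cycles/nm)")
        fig.colorbar(im, ax=ax, label="log10 squared Fourier magnitude")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


@dataclass
class RadialProfile:
    bin_centers: np.ndarray  # cycles/nm, strictly increasing
    mean_power: np.ndarray  # mean power per annulus (or sum, per weighting)
    percent_power: np.ndarray  # % of total (DC-excluded) power per annulus
    bin_width: float
    n_bar: float

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "frequency_cycles_per_nm": self.bin_centers,
            "mean_power": self.mean_power,
            "percent_power": self.percent_power,
        }).to_csv(path, index=False)


@dataclass
class PredictedSpectrum:
    wavelengths: np.ndarray  # nm, increasing
    reflectance: np.ndarray  # normalized predicted reflectance (% power)
    lambda_max: float  # visible-restricted peak (nm)
    lambda_max_unrestricted: float  # peak over the whole mappable range (nm)
    visible_band: tuple[float, float] = VISIBLE_BAND
    n_bar: float = float("nan")
    visible_freq_band: tuple[float, float] = field(default=(np.nan, np.nan))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "wavelength_nm": self.wavelengths,
            "predicted_reflectance": self.reflectance,
        }).to_csv(path, index=False)


def power_spectrum_2d(index_map: IndexMap, window: str | None = None) -> PowerSpectrum:
    """Centered squared-magnitude 2-D DFT of the mean-removed index matrix.

    Normalized so that the total power equals the sum of squared
    mean-removed index values (Parseval). No apodization by default;
    ``window="hann"`` applies a separable Hann window (changes peak
    widths, not locations).
    """
    n = np.asarray(index_map.n, dtype=float)
    rows, cols = n.shape
    if rows != cols:
        raise ValueError("index map must be square; crop first")
    if rows < 16:
        raise ValueError("index map must be at least 16x16")
    x = n - n.mean()
    if window == "hann":
        w = np.hanning(rows)
        x = x * np.outer(w, w)
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    f = np.fft.fftshift(np.fft.fft2(x))
    power = (np.abs(f) ** 2) / x.size
    # zero out the residual DC bin (mean removal leaves it ~0 numerically)
    power[rows // 2, rows // 2] = 0.0
    return PowerSpectrum(
        power=power,
        freq_step=1.0 / (rows * index_map.pixel_size),
        total_power=float(power.sum()),
        dc_removed=True,
        n_bar=index_map.n_bar,
    )


def radial_average(ps: PowerSpectrum, bin_width: float | None = None,
                   weighting: str = "mean") -> RadialProfile:
    """Average the power spectrum over annuli of constant |f|.

    Bin i covers |f| in [i*w - w/2, i*w + w/2), centered on integer
    multiples of the bin width; the default width is one frequency step,
    so an axis-aligned harmonic falls exactly on a bin center.
    ``weighting="mean"`` reports mean power per annulus (default);
    ``"sum"`` reports the annulus total.
    """
    if not ps.dc_removed:
        raise ValueError("power spectrum must have the DC component removed")
    w = ps.freq_step if bin_width is None else float(bin_width)
    n = ps.power.shape[0]
    nyquist = ps.freq_step * (n // 2)
    if w <= 0 or w > nyquist:
        raise ValueError("bin_width must be in (0, Nyquist]")

    c = n // 2
    idx = np.arange(n) - c
    fy, fx = np.meshgrid(idx * ps.freq_step, idx * ps.freq_step, indexing="ij")
    radius = np.hypot(fy, fx)
    bin_of = np.rint(radius / w).astype(int)

    # bins run out to the corner of the spectrum so no power is dropped
    nbins = int(bin_of.max()) + 1
    sums = np.bincount(bin_of.ravel(), weights=ps.power.ravel(), minlength=nbins)
    counts = np.bincount(bin_of.ravel(), minlength=nbins)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    values = means if weighting == "mean" else sums
    if weighting not in ("mean", "sum"):
        raise ValueError(f"unknown weighting {weighting!r}")

    total = ps.power.sum()
    percent = 100.0 * sums / total if total > 0 else np.zeros_like(sums)

    # drop the DC bin (index 0): profiles start at the first annulus
    centers = np.arange(1, nbins) * w
    return RadialProfile(bin_centers=centers, mean_power=values[1:],
                         percent_power=percent[1:], bin_width=w,
                         n_bar=ps.n_bar)


def frequency_to_wavelength(f: float | np.ndarray, n_bar: float):
    """Backscattered wavelength for index spatial frequency f: 2*n_bar/f."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("spatial frequency must be > 0")
    out = 2.0 * n_bar / f
    return float(out) if out.ndim == 0 else out


def visible_frequency_band(n_bar: float,
                           band: tuple[float, float] = VISIBLE_BAND) -> tuple[float, float]:
    """Spatial-frequency interval scattering coherently within the band."""
    lo, hi = band
    return (2.0 * n_bar / hi, 2.0 * n_bar / lo)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex abscissa of the parabola through points i-1, i, i+1."""
    if i <= 0 or i >= len(x) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0 or abs(denom) < 1e-300:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(x[i] + delta * (x[i] - x[i - 1]))


def _peak_frequency(centers: np.ndarray, power: np.ndarray,
                    lo: float | None, hi: float | None,
                    interpolate: bool) -> float | None:
    sel = np.ones_like(centers, dtype=bool)
    if lo is not None:
        sel &= centers >= lo
    if hi is not None:
        sel &= centers <= hi
    if not sel.any() or power[sel].max() <= 0:
        return None
    masked = np.where(sel, power, -np.inf)
    i = int(np.argmax(masked))
    if interpolate:
        return _parabolic_refine(centers, power, i)
    return float(centers[i])


def predicted_reflectance(profile: RadialProfile, n_bar: float | None = None,
                          interpolate_peak: bool = True) -> PredictedSpectrum:
    """Map a radial power profile to a predicted reflectance spectrum.

    Each frequency annulus maps to wavelength 2*n_bar/f; the annulus
    %power becomes the predicted (relative) reflectance at that
    wavelength. lambda_max is reported both restricted to the visible
    band (350-700 nm, the default headline value) and unrestricted.
    The peak frequency is refined by parabolic interpolation around the
    peak bin unless ``interpolate_peak=False``.
    """
    if n_bar is None:
        n_bar = profile.n_bar
    if not (1.0 < n_bar < 2.0):
        raise ValueError("n_bar must lie in (1, 2) for chitin/air tissue")
    centers = profile.bin_centers
    power = profile.percent_power
    if centers.size == 0:
        raise ValueError("empty radial profile")

    wavelengths = frequency_to_wavelength(centers, n_bar)
    order = np.argsort(wavelengths)
    f_lo, f_hi = visible_frequency_band(n_bar)

    f_peak_all = _peak_frequency(centers, power, None, None, interpolate_peak)
    if f_peak_all is None:
        raise ValueError("profile has no power in the mappable range")
    f_peak_vis = _peak_frequency(centers, power, f_lo, f_hi, interpolate_peak)

    lam_all = frequency_to_wavelength(f_peak_all, n_bar)
    lam_vis = frequency_to_wavelength(f_peak_vis, n_bar) if f_peak_vis else lam_all
    return PredictedSpectrum(
        wavelengths=wavelengths[order],
        reflectance=power[order],
        lambda_max=lam_vis,
        lambda_max_unrestricted=lam_all,
        n_bar=n_bar,
        visible_freq_band=(f_lo, f_hi),
    )


def analyze_index_map(index_map: IndexMap, bin_width: float | None = None,
                      window: str | None = None,
                      interpolate_peak: bool = True) -> PredictedSpectrum:
    """Convenience chain: power spectrum -> radial average -> prediction."""
    ps = power_spectrum_2d(index_map, window=window)
    profile = radial_average(ps, bin_width=bin_width)
    return predicted_reflectance(profile, interpolate_peak=interpolate_peak)
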