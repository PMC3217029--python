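"""Measured reflectance spectra: parsing, white-standard normalization,
and peak finding.

Reflectance microspectrophotometry records raw counts; dividing by the
spectrum of the light source recorded from a white diffuse standard
yields relative reflectance. Peaks are located on a lightly smoothed
spectrum with sub-grid parabolic refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ReflectanceSpectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    intensities: np.ndarray  # raw counts or normalized reflectance
    normalized: bool = False
    medium: str = "air"  # air | glycerine | ethanol

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelength and intensity arrays differ in length")
        if self.wavelengths.size < 3:
            raise ValueError("a spectrum needs at least 3 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.normalized and np.nanmin(self.intensities) < 0:
            raise ValueError("normalized reflectance must be >= 0")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths,
                      "intensity": self.intensities}).to_csv(path, index=False)


def read_spectrum(path: str | Path, medium: str = "air") -> ReflectanceSpectrum:
    """Parse a two-column (wavelength nm, intensity) CSV/TSV file.

    A single non-numeric header line is skipped automatically.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     comment="#", skip_blank_lines=True)
    # drop a header row if the first row fails numeric conversion
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    wl = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy()
    inten = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy()
    return ReflectanceSpectrum(wavelengths=wl, intensities=inten, medium=medium)


def normalize_to_white_standard(sample: ReflectanceSpectrum,
                                standard: ReflectanceSpectrum) -> ReflectanceSpectrum:
    """Pointwise ratio sample/standard on the overlapping wavelength range.

    The standard is linearly interpolated onto the sample grid (no
    extrapolation). Wavelengths where the standard records zero are
    masked to NaN with a warning.
    """
    lo = max(sample.wavelengths[0], standard.wavelengths[0])
    hi = min(sample.wavelengths[-1], standard.wavelengths[-1])
    if lo >= hi:
        raise ValueError("sample and standard wavelength ranges do not overlap")
    sel = (sample.wavelengths >= lo) & (sample.wavelengths <= hi)
    if sel.sum() < 3:
        raise ValueError("overlap contains fewer than 3 points")
    wl = sample.wavelengths[sel]
    std = np.interp(wl, standard.wavelengths, standard.intensities)
    ratio = np.empty_like(std)
    zero = std == 0
    if zero.any():
        warnings.warn(f"white standard is zero at {int(zero.sum())} wavelength(s); "
                      "those points are masked", stacklevel=2)
    ratio[~zero] = sample.intensities[sel][~zero] / std[~zero]
    ratio[zero] = np.nan
    return ReflectanceSpectrum(wavelengths=wl, intensities=ratio,
                               normalized=True, medium=sample.medium)


def find_peak(spec: ReflectanceSpectrum, smooth_window: int = 5) -> float:
    """Wavelength of maximum reflectance after moving-average smoothing.

    The window must be odd; the peak is refined by fitting a parabola
    through the three smoothed points around the argmax.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    y = np.asarray(spec.intensities, dtype=float)
    x = spec.wavelengths
    valid = np.isfinite(y)
    x, y = x[valid], y[valid]
    if y.size < smooth_window:
        raise ValueError("spectrum shorter than the smoothing window")
    if np.ptp(y) == 0:
        raise ValueError("no unique peak: spectrum is flat")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        # reflect-pad so the smoothed series keeps full length
        half = smooth_window // 2
        ypad = np.concatenate([y[half:0:-1], y, y[-2:-half - 2:-1]])
        y = np.convolve(ypad, kernel, mode="valid")
    i = int(np.argmax(y))
    if 0 < i < len(x) - 1:
        # quadratic through three (possibly non-uniform) abscissae
        coeff = np.polyfit(x[i - 1:i + 2], y[i - 1:i + 2], 2)
        if coeff[0] < 0:
            vertex = -coeff[1] / (2 * coeff[0])
            if x[i - 1] <= vertex <= x[i + 1]:
                return float(vertex)
    return float(x[i])
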