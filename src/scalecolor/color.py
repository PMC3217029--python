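"""Wavelength -> RGB conversion and wing-zone color reconstruction.

A predicted reflectance peak is a single dominant wavelength; mapping
that to a display RGB is inherently approximate, so three independent
conversions are computed and averaged:

* ``bruton`` — Dan Bruton's piecewise-linear visible-spectrum
  approximation (380-780 nm) with intensity fall-off at the band edges
  and display gamma 0.8;
* ``cie`` — CIE 1931 2-degree color-matching functions (the analytic
  multi-lobe Gaussian fit of Wyman, Sloan & Shirley 2013) evaluated at
  the single wavelength, converted to linear sRGB with gamut clipping,
  brightness-normalized and sRGB-encoded;
* ``bruton_g1`` — the Bruton formula with gamma 1.0 (a gamma variant).

Outside 380-780 nm every method returns black (0, 0, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_METHODS = ("bruton", "cie", "bruton_g1")


@dataclass(frozen=True)
class RGBColor:
    r: int
    g: int
    b: int
    method: str = ""

    def __post_init__(self) -> None:
        for v in (self.r, self.g, self.b):
            if not (0 <= v <= 255):
                raise ValueError("RGB components must lie in 0-255")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.r, self.g, self.b)


@dataclass
class ZoneColorMap:
    """Ordered (zone name, lambda_max nm, consensus color) entries."""

    entries: list[tuple[str, float, RGBColor]]

    def __post_init__(self) -> None:
        names = [z for z, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("zone names must be unique")
        if any(lam <= 0 for _, lam, _ in self.entries):
            raise ValueError("lambda_max must be positive")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(z, lam, c.r, c.g, c.b) for z, lam, c in self.entries],
            columns=["zone", "lambda_max_nm", "r", "g", "b"],
        ).to_csv(path, index=False)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _bruton_components(lam: float) -> tuple[float, float, float]:
    if 380 <= lam < 440:
        return (-(lam - 440) / 60.0, 0.0, 1.0)
    if 440 <= lam < 490:
        return (0.0, (lam - 440) / 50.0, 1.0)
    if 490 <= lam < 510:
        return (0.0, 1.0, -(lam - 510) / 20.0)
    if 510 <= lam < 580:
        return ((lam - 510) / 70.0, 1.0, 0.0)
    if 580 <= lam < 645:
        return (1.0, -(lam - 645) / 65.0, 0.0)
    if 645 <= lam <= 780:
        return (1.0, 0.0, 0.0)
    return (0.0, 0.0, 0.0)


def _bruton_factor(lam: float) -> float:
    if 380 <= lam < 420:
        return 0.3 + 0.7 * (lam - 380) / 40.0
    if 420 <= lam <= 700:
        return 1.0
    if 700 < lam <= 780:
        return 0.3 + 0.7 * (780 - lam) / 80.0
    return 0.0


def _bruton_rgb(lam: float, gamma: float) -> tuple[int, int, int]:
    factor = _bruton_factor(lam)
    out = []
    for c in _bruton_components(lam):
        v = factor * c
        out.append(_round_half_up((v ** gamma if v > 0 else 0.0) * 255))
    return tuple(out)


def _piecewise_gauss(x: float, alpha: float, mu: float,
                     sigma1: float, sigma2: float) -> float:
    sigma = sigma1 if x < mu else sigma2
    return alpha * math.exp(-0.5 * ((x - mu) / sigma) ** 2)


def cie_xyz(lam: float) -> tuple[float, float, float]:
    """CIE 1931 2-degree tristimulus of a monochromatic stimulus (analytic fit)."""
    x = (_piecewise_gauss(lam, 1.056, 599.8, 37.9, 31.0)
         + _piecewise_gauss(lam, 0.362, 442.0, 16.0, 26.7)
         - _piecewise_gauss(lam, 0.065, 501.1, 20.4, 26.2))
    y = (_piecewise_gauss(lam, 0.821, 568.8, 46.9, 40.5)
         + _piecewise_gauss(lam, 0.286, 530.9, 16.3, 31.1))
    z = (_piecewise_gauss(lam, 1.217, 437.0, 11.8, 36.0)
         + _piecewise_gauss(lam, 0.681, 459.0, 26.0, 13.8))
    return (x, y, z)


# linear sRGB (D65) from XYZ
_XYZ_TO_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


def _srgb_encode(v: float) -> float:
    if v <= 0.0031308:
        return 12.92 * v
    return 1.055 * v ** (1 / 2.4) - 0.055


def _cie_rgb(lam: float) -> tuple[int, int, int]:
    xyz = np.array(cie_xyz(lam))
    rgb = _XYZ_TO_SRGB @ xyz
    rgb = np.clip(rgb, 0.0, None)  # gamut clipping, not normalization of hue
    peak = rgb.max()
    if peak <= 0:
        return (0, 0, 0)
    rgb = rgb / peak  # brightness-normalize the monochromatic stimulus
    return tuple(_round_half_up(_srgb_encode(v) * 255) for v in rgb)


def wavelength_to_rgb(lam: float, method: str = "bruton") -> RGBColor:
    """Convert a dominant wavelength (nm) to an 8-bit RGB color."""
    if lam <= 0:
        raise ValueError("wavelength must be positive")
    if not (380.0 <= lam <= 780.0):
        return RGBColor(0, 0, 0, method=method)
    if method == "bruton":
        r, g, b = _bruton_rgb(lam, gamma=0.8)
    elif method == "bruton_g1":
        r, g, b = _bruton_rgb(lam, gamma=1.0)
    elif method == "cie":
        r, g, b = _cie_rgb(lam)
    else:
        raise ValueError(f"unknown method {method!r}")
    return RGBColor(r, g, b, method=method)


def average_colors(colors: Iterable[RGBColor], label: str = "average") -> RGBColor:
    """Component-wise arithmetic mean, rounded half-up."""
    colors = list(colors)
    if not colors:
        raise ValueError("at least one color is required")
    n = len(colors)
    return RGBColor(
        _round_half_up(sum(c.r for c in colors) / n),
        _round_half_up(sum(c.g for c in colors) / n),
        _round_half_up(sum(c.b for c in colors) / n),
        method=label,
    )


def consensus_rgb(lam: float,
                  methods: Sequence[str] = DEFAULT_METHODS) -> RGBColor:
    """Mean of the per-method conversions of a single wavelength."""
    if not methods:
        raise ValueError("at least one conversion method is required")
    return average_colors((wavelength_to_rgb(lam, m) for m in methods),
                          label="consensus:" + "+".join(methods))


def render_reconstruction(color_map: ZoneColorMap, out_path: str | Path) -> Path:
    """Write a labeled swatch panel (one rectangle per zone) as PNG or SVG."""
    if not color_map.entries:
        raise ValueError("empty zone color map")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    n = len(color_map.entries)
    fig, ax = plt.subplots(figsize=(max(2.0, 1.8 * n), 2.6))
    for i, (zone, lam, color) in enumerate(color_map.entries):
        ax.add_patch(Rectangle((i, 0), 0.92, 1.0,
                               facecolor=np.array(color.as_tuple()) / 255.0,
                               edgecolor="black", linewidth=0.5))
        ax.text(i + 0.46, -0.12, zone, ha="center", va="top", fontsize=9)
        ax.text(i + 0.46, 1.06, f"{lam:.0f} nm", ha="center", va="bottom",
                fontsize=8)
    ax.set_xlim(-0.1, n)
    ax.set_ylim(-0.45, 1.35)
    ax.axis("off")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path
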