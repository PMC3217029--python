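"""Micrograph preparation: grayscale raster -> two-phase refractive-index map.

The coherent-scattering analysis operates on a matrix of refractive
indices. A TEM micrograph of a chitin/air nanostructure is first
thresholded into a binary phase map (chitin vs medium), then each
phase is assigned its index: ~1.56 for lepidopteran cuticle, 1.0 for
air. The volume-weighted mean index n_bar of the analyzed region is
carried along for the frequency-to-wavelength mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.filters import threshold_otsu

N_HIGH_DEFAULT = 1.56
N_LOW_DEFAULT = 1.0


@dataclass
class RasterImage:
    pixels: np.ndarray  # 2-D grayscale, any integer/float dtype
    pixel_size: float  # nm per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("image must be 2-D and at least 2x2 pixels")
        if self.pixel_size is None or self.pixel_size <= 0:
            raise ValueError("pixel_size (nm/px) must be supplied and > 0")


@dataclass
class PhaseMap:
    """Binary mask: 1 = high-index phase (chitin), 0 = low-index medium."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(np.uint8)
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("phase mask must be binary")
        if vals.size < 2:
            raise ValueError("degenerate: single phase")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def fill_fraction(self) -> float:
        """High-index (chitin) area fraction."""
        return float(self.mask.mean())

    def inverted(self) -> "PhaseMap":
        return PhaseMap(mask=1 - self.mask, pixel_size=self.pixel_size)

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.mask * 255, mode="L").save(path)


@dataclass
class IndexMap:
    """2-D refractive-index matrix with its volume-weighted mean index."""

    n: np.ndarray
    n_high: float
    n_low: float
    n_bar: float
    pixel_size: float


def load_image(path: str | Path, pixel_size: float,
               convert_gray: bool = False) -> RasterImage:
    """Read an 8/16-bit grayscale TIFF or PNG.

    The pixel scale (nm/px) always comes from the caller: TEM calibration
    lives in figure scale bars, not in the files themselves. Color input
    is an error unless ``convert_gray`` explicitly requests luminance
    conversion.
    """
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("pixel_size (nm/px) must be supplied and > 0")
    with Image.open(path) as im:
        if im.mode in ("L", "I", "I;16", "I;16B", "F"):
            arr = np.asarray(im)
        elif convert_gray:
            arr = np.asarray(im.convert("L"))
        else:
            raise ValueError(
                f"{path}: mode {im.mode} is not grayscale; "
                "pass convert_gray=True to convert"
            )
    return RasterImage(pixels=arr, pixel_size=pixel_size)


def binarize_phases(img: RasterImage, method: str = "otsu",
                    threshold: float | None = None,
                    invert: bool = False) -> PhaseMap:
    """Threshold a micrograph into high/low-index phases.

    The brighter phase maps to 1 (high index) by default; ``invert``
    flips the assignment for micrographs where the dense phase is dark
    (contrast polarity varies with staining and imaging mode).
    """
    px = np.asarray(img.pixels, dtype=float)
    if np.ptp(px) == 0:
        raise ValueError("degenerate: single phase (constant image)")
    if method == "otsu":
        thr = threshold_otsu(px)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires an explicit threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = (px > thr).astype(np.uint8)
    if invert:
        mask = 1 - mask
    if np.unique(mask).size < 2:
        raise ValueError("degenerate: threshold yields a single phase")
    return PhaseMap(mask=mask, pixel_size=img.pixel_size)


def build_index_map(phase: PhaseMap, n_high: float = N_HIGH_DEFAULT,
                    n_low: float = N_LOW_DEFAULT) -> IndexMap:
    """Assign refractive indices to the two phases; n_bar is area-weighted."""
    if n_high <= n_low:
        raise ValueError("n_high must exceed n_low")
    if n_low <= 0:
        raise ValueError("indices must be positive")
    n = np.where(phase.mask == 1, n_high, n_low)
    fill = phase.fill_fraction
    n_bar = fill * n_high + (1.0 - fill) * n_low
    return IndexMap(n=n, n_high=n_high, n_low=n_low, n_bar=n_bar,
                    pixel_size=phase.pixel_size)


def select_square_region(obj, size_px: int, origin: str | tuple[int, int] = "centered"):
    """Crop a square region from a RasterImage or PhaseMap.

    ``origin`` is either ``"centered"`` or a (row, col) top-left offset.
    """
    if isinstance(obj, RasterImage):
        data, rebuild = obj.pixels, lambda a: RasterImage(a, obj.pixel_size)
    elif isinstance(obj, PhaseMap):
        data, rebuild = obj.mask, lambda a: PhaseMap(a, obj.pixel_size)
    else:
        raise TypeError("expected RasterImage or PhaseMap")
    h, w = data.shape
    if size_px > h or size_px > w:
        raise ValueError(f"crop {size_px} exceeds image {h}x{w}")
    if origin == "centered":
        r0, c0 = (h - size_px) // 2, (w - size_px) // 2
    else:
        r0, c0 = origin
        if r0 < 0 or c0 < 0 or r0 + size_px > h or c0 + size_px > w:
            raise ValueError("offset crop falls outside the image")
    return rebuild(data[r0:r0 + size_px, c0:c0 + size_px])
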