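"""Synthetic nanostructure images with known ground truth.

Emulates TEM cross-sections of the photonic architecture found in
lepidopteran scale lumina: a stack of alternating chitin/air laminae
(a multilayer reflector) and perforated lamina surfaces. Every
generated image carries the true geometry (period, fill fraction,
open-area fraction, ideal reflectance peak) so each downstream stage
of the analysis can be tested against a closed-form answer.

Realistic lamina thicknesses for this system: uppermost lamina
93-124 nm, lower laminae thinning from 74-110 nm down to 55-63 nm.
Air-gap thickness is not directly observable in fossil material and
is a free parameter here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

HIGH = "high"
LOW = "low"

#: default refractive indices: chitin-like cuticle vs air
N_HIGH_DEFAULT = 1.56
N_LOW_DEFAULT = 1.0


@dataclass(frozen=True)
class MultilayerSpec:
    """Geometry of a synthetic multilayer-reflector cross-section.

    ``layers`` is the unit cell: ordered (thickness_nm, phase) pairs with
    phase ``"high"`` or ``"low"``; the cell is repeated ``periods`` times
    from the top of the raster downward.
    """

    layers: Sequence[tuple[float, str]]
    periods: int
    pixel_size: float  # nm per pixel
    width_px: int
    curvature_radius: float = math.inf  # nm; inf = flat laminae
    noise_sd: float = 0.0  # grayscale units
    intensity_high: int = 200  # chitin phase rendered bright by default
    intensity_low: int = 55
    seed: int = 0
    margin_px: int = 0  # low-phase padding above/below the stack

    MAX_RASTER = 8192  # practical bound on either dimension

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer is required")
        for d, phase in self.layers:
            if d <= 0:
                raise ValueError(f"layer thickness must be > 0, got {d}")
            if phase not in (HIGH, LOW):
                raise ValueError(f"phase must be 'high' or 'low', got {phase!r}")
        if self.periods < 1:
            raise ValueError("periods must be a positive integer")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.width_px < 1:
            raise ValueError("width_px must be positive")
        if self.intensity_high == self.intensity_low:
            raise ValueError("intensity_high must differ from intensity_low")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.curvature_radius <= 0:
            raise ValueError("curvature_radius must be > 0 (use inf for flat)")
        height = self.height_px
        if height > self.MAX_RASTER or self.width_px > self.MAX_RASTER:
            raise ValueError(
                f"raster {height}x{self.width_px} exceeds bound {self.MAX_RASTER}"
            )

    @property
    def period_nm(self) -> float:
        return float(sum(d for d, _ in self.layers))

    @property
    def height_px(self) -> int:
        stack = self.periods * self.period_nm / self.pixel_size
        return int(round(stack)) + 2 * self.margin_px

    def ideal_peak_nm(self, n_high: float = N_HIGH_DEFAULT,
                      n_low: float = N_LOW_DEFAULT) -> float:
        """Fundamental normal-incidence reflectance peak, 2*sum(n_j d_j)."""
        n = {HIGH: n_high, LOW: n_low}
        return 2.0 * sum(n[phase] * d for d, phase in self.layers)

    def fill_fraction(self) -> float:
        high = sum(d for d, phase in self.layers if phase == HIGH)
        return high / self.period_nm


@dataclass(frozen=True)
class PerforatedLaminaSpec:
    """Binary lamina surface with circular perforations on a square grid."""

    width_px: int
    height_px: int
    pitch_px: int
    hole_radius_px: float
    jitter_sd_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("lamina dimensions must be positive")
        if self.pitch_px < 1:
            raise ValueError("pitch_px must be positive")
        if self.pitch_px > min(self.width_px, self.height_px):
            raise ValueError("pitch_px must not exceed either image dimension")
        if self.hole_radius_px < 0:
            raise ValueError("hole_radius_px must be >= 0")
        if self.hole_radius_px >= self.pitch_px / 2:
            raise ValueError("hole_radius_px must be < pitch_px/2")
        if self.jitter_sd_px < 0:
            raise ValueError("jitter_sd_px must be >= 0")


@dataclass
class SyntheticImage:
    """Generated raster plus the ground truth it was built from."""

    pixels: np.ndarray  # 2-D uint8
    pixel_size: float  # nm/px
    ground_truth: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        """Write an 8-bit grayscale PNG/TIFF plus a JSON ground-truth sidecar."""
        path = Path(path)
        Image.fromarray(self.pixels, mode="L").save(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        record = {"pixel_size_nm": self.pixel_size, **self.ground_truth}
        sidecar.write_text(json.dumps(record, indent=2, sort_keys=True))


def _layer_profile(spec: MultilayerSpec) -> np.ndarray:
    """1-D phase profile (bool, True = high phase) down the stack.

    Layer boundaries are placed by rounding the running sum of thicknesses,
    so the accumulated length error over any number of periods stays <= 1 px.
    """
    height = spec.height_px
    profile = np.zeros(height, dtype=bool)  # background = low phase
    pos_nm = spec.margin_px * spec.pixel_size
    for _ in range(spec.periods):
        for d, phase in spec.layers:
            start = int(round(pos_nm / spec.pixel_size))
            pos_nm += d
            stop = int(round(pos_nm / spec.pixel_size))
            if phase == HIGH:
                profile[start:min(stop, height)] = True
    return profile


def generate_multilayer_image(spec: MultilayerSpec) -> SyntheticImage:
    """Render a multilayer cross-section as horizontal bands.

    Bands of alternating intensity run left-right; optional concave
    curvature displaces band midlines downward by the sagitta of a
    circular arc; Gaussian noise is added last and clipped to 0-255.
    """
    profile = _layer_profile(spec)
    height = spec.height_px

    if math.isinf(spec.curvature_radius):
        mask = np.tile(profile[:, None], (1, spec.width_px))
    else:
        radius_px = spec.curvature_radius / spec.pixel_size
        x = np.arange(spec.width_px, dtype=float) - (spec.width_px - 1) / 2.0
        if np.abs(x).max() >= radius_px:
            raise ValueError("curvature_radius too small for image width")
        sag = radius_px - np.sqrt(radius_px**2 - x**2)
        rows = np.arange(height)[:, None] - np.round(sag)[None, :].astype(int)
        rows = np.clip(rows, 0, height - 1)
        mask = profile[rows]

    img = np.where(mask, spec.intensity_high, spec.intensity_low).astype(float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = {
        "kind": "multilayer",
        "period_nm": spec.period_nm,
        "fill_fraction": spec.fill_fraction(),
        "ideal_peak_nm": spec.ideal_peak_nm(),
        "n_high": N_HIGH_DEFAULT,
        "n_low": N_LOW_DEFAULT,
        "periods": spec.periods,
        "layers_nm": [[d, phase] for d, phase in spec.layers],
        "high_is_bright": spec.intensity_high > spec.intensity_low,
        "phase_mask_fill": float(mask.mean()),
    }
    return SyntheticImage(pixels=pixels, pixel_size=spec.pixel_size,
                          ground_truth=truth)


def multilayer_phase_mask(spec: MultilayerSpec) -> np.ndarray:
    """Ground-truth boolean mask (True = high phase) for a flat stack."""
    if not math.isinf(spec.curvature_radius):
        raise ValueError("ground-truth mask only defined for flat stacks")
    return np.tile(_layer_profile(spec)[:, None], (1, spec.width_px))


def generate_perforated_lamina(spec: PerforatedLaminaSpec) -> SyntheticImage:
    """Render a solid lamina (255) with circular open holes (0).

    Hole centers sit on a square grid of pitch ``pitch_px`` (cell centers),
    optionally jittered by a Gaussian of sd ``jitter_sd_px``. A jittered
    hole that would cross its cell boundary (touching its neighbor) is an
    error rather than silently clipped.
    """
    h, w, pitch = spec.height_px, spec.width_px, spec.pitch_px
    r = spec.hole_radius_px
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    open_mask = np.zeros((h, w), dtype=bool)
    half = (pitch - 1) / 2.0
    max_shift = pitch / 2.0 - r
    for i in range(h // pitch):
        for j in range(w // pitch):
            cy, cx = i * pitch + half, j * pitch + half
            if spec.jitter_sd_px > 0:
                dy, dx = rng.normal(0.0, spec.jitter_sd_px, 2)
                if math.hypot(dy, dx) > max_shift:
                    raise ValueError(
                        f"jitter displaces hole ({i},{j}) beyond its pitch cell"
                    )
                cy, cx = cy + dy, cx + dx
            if r > 0:
                open_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r

    pixels = np.where(open_mask, 0, 255).astype(np.uint8)
    truth = {
        "kind": "perforated_lamina",
        "open_fraction": float(open_mask.mean()),
        "pitch_px": pitch,
        "hole_radius_px": r,
        "analytic_open_fraction": math.pi * r * r / pitch**2,
    }
    return SyntheticImage(pixels=pixels, pixel_size=1.0, ground_truth=truth)
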