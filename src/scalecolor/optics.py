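"""Scale morphometrics and closed-form thin-film optics.

Three independent physical yardsticks for the Fourier pipeline:

* the lamina perforation factor p (open-area fraction), which governs
  iridescence and reflectance intensity;
* diffraction-order counting from the grating equation, used to decide
  whether a periodic surface element (microribs, ridges) diffracts
  visible light at all;
* ideal-multilayer and transfer-matrix reflectance of a chitin/air
  stack — closed-form oracles for the peak position and for the
  non-ideality (peak reflectance well below 100%) of thin, unequal
  stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_prep import PhaseMap


@dataclass(frozen=True)
class PerforationStats:
    p: float  # open-area fraction in [0, 1]
    open_pixels: int
    total_pixels: int


@dataclass(frozen=True)
class GratingSpec:
    period_d: float  # nm
    incidence_angle: float = 0.0  # degrees from normal

    def __post_init__(self) -> None:
        if self.period_d <= 0:
            raise ValueError("grating period must be > 0")
        if not (-90 < self.incidence_angle < 90):
            raise ValueError("incidence angle must lie strictly within ±90°")


@dataclass(frozen=True)
class StackSpec:
    """Layer stack for the characteristic-matrix reflectance calculation."""

    layers: Sequence[tuple[float, float]]  # (refractive index, thickness nm)
    n_ambient: float = 1.0
    n_substrate: float = 1.0

    def __post_init__(self) -> None:
        for n, d in self.layers:
            if n < 1:
                raise ValueError("layer indices must be >= 1")
            if d <= 0:
                raise ValueError("layer thicknesses must be > 0")
        if self.n_ambient < 1 or self.n_substrate < 1:
            raise ValueError("ambient/substrate indices must be >= 1")

    @classmethod
    def bilayers(cls, n1: float, d1: float, n2: float, d2: float,
                 count: int, n_ambient: float = 1.0,
                 n_substrate: float = 1.0) -> "StackSpec":
        layers = [(n1, d1), (n2, d2)] * count
        return cls(layers=layers, n_ambient=n_ambient, n_substrate=n_substrate)


def perforation_factor(phase: PhaseMap, invert: bool = False) -> PerforationStats:
    """Open-area fraction of a lamina mask.

    Convention: mask value 0 (dark/absent phase) is open; ``invert``
    for the opposite contrast.
    """
    mask = np.asarray(phase.mask)
    if mask.size == 0:
        raise ValueError("empty region")
    open_mask = (mask == 1) if invert else (mask == 0)
    open_px = int(open_mask.sum())
    return PerforationStats(p=open_px / mask.size, open_pixels=open_px,
                            total_pixels=int(mask.size))


def open_fraction(mask: np.ndarray) -> float:
    """Open-area fraction of a raw binary array (nonzero = solid)."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty region")
    return float((mask == 0).mean())


def propagating_orders(grating: GratingSpec, lam: float) -> int:
    """Number of nonzero diffraction orders the grating can propagate.

    Counts integers m != 0 with |sin(theta_i) + m*lambda/d| <= 1 (both
    signs). Zero means only specular (zero-order) reflection exists —
    the sub-wavelength regime.
    """
    if lam <= 0:
        raise ValueError("wavelength must be > 0")
    s = math.sin(math.radians(grating.incidence_angle))
    ratio = lam / grating.period_d
    count = 0
    m = 1
    while True:
        found = False
        for mm in (m, -m):
            if abs(s + mm * ratio) <= 1.0:
                count += 1
                found = True
        if not found:
            break
        m += 1
    return count


def ideal_multilayer_peak(d1: float, n1: float, d2: float, n2: float) -> float:
    """Fundamental normal-incidence peak of an infinite periodic bilayer stack.

    lambda = 2*(n1*d1 + n2*d2); for quarter-wave layers d_j = lambda0/(4 n_j)
    this returns exactly lambda0.
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError("thicknesses must be > 0")
    if n1 < 1 or n2 < 1:
        raise ValueError("indices must be >= 1")
    return 2.0 * (n1 * d1 + n2 * d2)


def transfer_matrix_reflectance(stack: StackSpec,
                                lambda_grid: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normal-incidence reflectance of a layer stack (characteristic matrices).

    Per layer at wavelength lambda the phase thickness is
    delta_j = 2*pi*n_j*d_j/lambda and the characteristic matrix
    [[cos d, i sin d / n], [i n sin d, cos d]]; the product over layers
    with the ambient and substrate admittances gives the amplitude
    reflectance, squared for intensity. Non-absorbing (real) indices.
    """
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size == 0:
        raise ValueError("empty wavelength grid")
    if np.any(lam <= 0):
        raise ValueError("wavelengths must be > 0")

    out = np.empty(lam.shape, dtype=float)
    for k, wl in np.ndenumerate(lam):
        m = np.eye(2, dtype=complex)
        for n_j, d_j in stack.layers:
            delta = 2.0 * math.pi * n_j * d_j / wl
            c, s = math.cos(delta), math.sin(delta)
            m = m @ np.array([[c, 1j * s / n_j], [1j * n_j * s, c]])
        na, ns = stack.n_ambient, stack.n_substrate
        b = m[0, 0] + m[0, 1] * ns
        c2 = m[1, 0] + m[1, 1] * ns
        r = (na * b - c2) / (na * b + c2)
        out[k] = abs(r) ** 2
    return out
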