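"""Config-driven end-to-end color reconstruction.

For each wing zone the pipeline analyzes one to a few replicate
cross-section micrographs: load -> square crop -> phase segmentation
-> refractive-index map -> 2-D Fourier power spectrum -> radial
average -> predicted reflectance -> lambda_max. The zone's predicted
peak is the mean over replicates and is converted to a consensus RGB;
the run emits a JSON report, a CSV table, and a rendered swatch panel.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .color import (
    DEFAULT_METHODS,
    RGBColor,
    ZoneColorMap,
    consensus_rgb,
    render_reconstruction,
)
from .fourier import analyze_index_map
from .image_prep import (
    binarize_phases,
    build_index_map,
    load_image,
    select_square_region,
)

log = logging.getLogger("scalecolor")


@dataclass
class ZoneConfig:
    name: str
    images: list[str]
    pixel_size: float  # nm/px

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError(f"zone {self.name!r} lists no images")
        if self.pixel_size <= 0:
            raise ValueError(f"zone {self.name!r}: pixel_size must be > 0")


@dataclass
class RunConfig:
    zones: list[ZoneConfig]
    n_high: float = 1.56
    n_low: float = 1.0
    crop_size: int | None = None  # None = largest centered square
    bin_width: float | None = None  # cycles/nm; None = one frequency step
    window: str | None = None
    interpolate_peak: bool = True
    invert_contrast: bool = False
    threshold_method: str = "otsu"
    rgb_methods: Sequence[str] = DEFAULT_METHODS
    aggregate: str = "mean"  # mean | median
    restrict_visible: bool = True
    out_dir: str = "scalecolor_out"
    seed: int = 0
    deterministic: bool = False  # suppress timestamps for byte-identical reports

    def __post_init__(self) -> None:
        if not self.zones:
            raise ValueError("config must define at least one zone")
        if self.n_high <= self.n_low:
            raise ValueError("n_high must exceed n_low")
        if self.aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON run configuration."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        zones = [ZoneConfig(**z) for z in data.pop("zones")]
        return cls(zones=zones, **data)


@dataclass
class ZoneResult:
    name: str
    lambda_max_replicates: list[float]
    lambda_max_mean: float
    lambda_max_median: float
    lambda_max_range: tuple[float, float]
    lambda_max_unrestricted: list[float]
    n_bar_replicates: list[float]
    rgb: tuple[int, int, int]
    flags: list[str] = field(default_factory=list)


def analyze_image(path: str | Path, pixel_size: float, *,
                  n_high: float = 1.56, n_low: float = 1.0,
                  crop_size: int | None = None,
                  threshold_method: str = "otsu",
                  invert_contrast: bool = False,
                  bin_width: float | None = None,
                  window: str | None = None,
                  interpolate_peak: bool = True):
    """Single-image analysis: micrograph -> PredictedSpectrum."""
    img = load_image(path, pixel_size)
    h, w = img.pixels.shape
    size = min(h, w) if crop_size is None else crop_size
    img = select_square_region(img, size)
    phase = binarize_phases(img, method=threshold_method,
                            invert=invert_contrast)
    imap = build_index_map(phase, n_high=n_high, n_low=n_low)
    return analyze_index_map(imap, bin_width=bin_width, window=window,
                             interpolate_peak=interpolate_peak)


def run_reconstruction(config: RunConfig) -> dict:
    """Execute the full reconstruction; returns the report dict.

    Artifacts written to ``config.out_dir``: report.json, zones.csv,
    reconstruction.png. A zone whose segmentation degenerates is
    flagged and skipped in the rendering; an unreadable image aborts
    with an error naming the zone and path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: list[ZoneResult] = []

    for zone in config.zones:
        t0 = time.perf_counter()
        lams, lams_all, nbars, flags = [], [], [], []
        for img_path in zone.images:
            if not Path(img_path).exists():
                raise FileNotFoundError(
                    f"zone {zone.name!r}: image not found: {img_path}")
            try:
                spec = analyze_image(
                    img_path, zone.pixel_size,
                    n_high=config.n_high, n_low=config.n_low,
                    crop_size=config.crop_size,
                    threshold_method=config.threshold_method,
                    invert_contrast=config.invert_contrast,
                    bin_width=config.bin_width, window=config.window,
                    interpolate_peak=config.interpolate_peak,
                )
            except ValueError as exc:
                flags.append(f"{img_path}: {exc}")
                continue
            lams.append(spec.lambda_max if config.restrict_visible
                        else spec.lambda_max_unrestricted)
            lams_all.append(spec.lambda_max_unrestricted)
            nbars.append(spec.n_bar)

        if not lams:
            results.append(ZoneResult(zone.name, [], float("nan"),
                                      float("nan"), (float("nan"),) * 2,
                                      [], [], (0, 0, 0),
                                      flags or ["no analyzable replicate"]))
            continue

        mean = sum(lams) / len(lams)
        median = sorted(lams)[len(lams) // 2] if len(lams) % 2 else \
            sum(sorted(lams)[len(lams) // 2 - 1:len(lams) // 2 + 1]) / 2
        agg = mean if config.aggregate == "mean" else median
        rgb = consensus_rgb(agg, config.rgb_methods)
        results.append(ZoneResult(
            name=zone.name, lambda_max_replicates=lams,
            lambda_max_mean=mean, lambda_max_median=median,
            lambda_max_range=(min(lams), max(lams)),
            lambda_max_unrestricted=lams_all, n_bar_replicates=nbars,
            rgb=rgb.as_tuple(), flags=flags,
        ))
        log.info("zone %s: lambda_max %.1f nm (%d replicates, %.2f s)",
                 zone.name, agg, len(lams), time.perf_counter() - t0)

    report = {
        "software": {"name": "scalecolor", "version": __version__},
        "config": {
            "n_high": config.n_high, "n_low": config.n_low,
            "crop_size": config.crop_size, "bin_width": config.bin_width,
            "window": config.window,
            "interpolate_peak": config.interpolate_peak,
            "invert_contrast": config.invert_contrast,
            "threshold_method": config.threshold_method,
            "rgb_methods": list(config.rgb_methods),
            "aggregate": config.aggregate,
            "restrict_visible": config.restrict_visible,
            "seed": config.seed,
        },
        "zones": [
            {
                "zone": r.name,
                "lambda_max_nm": r.lambda_max_mean if config.aggregate == "mean"
                else r.lambda_max_median,
                "lambda_max_replicates_nm": r.lambda_max_replicates,
                "lambda_max_range_nm": list(r.lambda_max_range),
                "lambda_max_unrestricted_nm": r.lambda_max_unrestricted,
                "n_bar_replicates": r.n_bar_replicates,
                "consensus_rgb": list(r.rgb),
                "flags": r.flags,
            }
            for r in results
        ],
    }
    if not config.deterministic:
        report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    (out / "report.json").write_text(json.dumps(report, indent=2))
    pd.DataFrame([
        {"zone": r.name,
         "lambda_max_nm": r.lambda_max_mean if config.aggregate == "mean"
         else r.lambda_max_median,
         "r": r.rgb[0], "g": r.rgb[1], "b": r.rgb[2]}
        for r in results
    ]).to_csv(out / "zones.csv", index=False)

    drawable = [(r.name,
                 r.lambda_max_mean if config.aggregate == "mean"
                 else r.lambda_max_median,
                 RGBColor(*r.rgb))
                for r in results if r.lambda_max_replicates]
    if drawable:
        render_reconstruction(ZoneColorMap(entries=drawable),
                              out / "reconstruction.png")
    return report


def setup_logging(quiet: bool = False) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.WARNING if quiet else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
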