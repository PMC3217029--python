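import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from scalecolor.image_prep import RasterImage, binarize_phases, build_index_map
from scalecolor.synthetic import MultilayerSpec, generate_multilayer_image


def bilayer_spec(high_nm, low_nm, periods=5, pixel_size=1.0, **kw):
    """Square synthetic chitin/air multilayer cross-section spec."""
    height = int(round(periods * (high_nm + low_nm) / pixel_size))
    kw.setdefault("width_px", height)
    return MultilayerSpec(layers=[(high_nm, "high"), (low_nm, "low")],
                          periods=periods, pixel_size=pixel_size, **kw)


def pipeline_index_map(spec):
    """Generated image -> thresholded phase map -> index map."""
    img = generate_multilayer_image(spec)
    raster = RasterImage(img.pixels, img.pixel_size)
    phase = binarize_phases(raster)
    return build_index_map(phase)


@pytest.fixture
def basal_spec():
    """The 110 nm chitin / 111 nm air stack predicting a 565 nm peak."""
    return bilayer_spec(110, 111)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
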