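import numpy as np
import pytest

from fspimix import ProfileImage, make_design

WATER = (70, 110, 150)
SEDIMENT = (25, 18, 12)
PINK = (255, 105, 180)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_design():
    """Two ratios + control, two replicates: 6 aquaria."""
    return make_design(
        ratios=((8, 0), (0, 8)), n_replicates=2,
        sampling_days=(0, 21), analysis_day=21,
    )


@pytest.fixture
def image_factory():
    """Hand-built profile images with a known flat interface.

    ``make(interface_row, pink_pixels)`` paints water above the interface,
    sediment below, then sets the listed (row, col) pixels pink.
    """

    def make(interface_row=50, pink_pixels=(), shape=(100, 40),
             resolution=0.07):
        img = np.zeros((*shape, 3), dtype=np.uint8)
        img[:interface_row] = WATER
        img[interface_row:] = SEDIMENT
        for r, c in pink_pixels:
            img[r, c] = PINK
        return ProfileImage(pixels=img, resolution_mm_per_px=resolution)

    return make
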