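import numpy as np
import pytest

from pomerate import fixtures as fx
from pomerate.raster import RasterImage
from pomerate.segment import SegmentedFruit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tray_18():
    """18-disc tray with ground-truth masks in tray order."""
    return fx.make_tray(18, rows=3, cols=6, seed=1)


@pytest.fixture(scope="session")
def card_line():
    """Noiseless 10-color card and its fitted reference line."""
    from pomerate.pear_color import fit_card_line

    pts, truth = fx.make_card(n=10, noise_sigma=0.0, seed=1)
    return pts, truth, fit_card_line(pts)


def uniform_fruit(rgb, h=40, w=40, pad=4):
    """A solid-color rectangle fruit on black background."""
    px = np.zeros((h + 2 * pad, w + 2 * pad, 3), dtype=np.uint8)
    px[pad:-pad, pad:-pad] = rgb
    return SegmentedFruit("uniform", 1, RasterImage(px), h * w)


@pytest.fixture
def mid_green_fruit():
    return uniform_fruit((80, 150, 70))
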