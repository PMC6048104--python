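import numpy as np
import pytest

from shapecut.volume_io import LabelVolume, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """A 9x9x9 random intensity volume with unit spacing."""
    return Volume(rng.random((9, 9, 9)) * 100.0)


def make_ball_mask(shape, center, radius):
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


@pytest.fixture
def ball_label():
    """A radius-10 ball in a 28^3 grid, unit spacing."""
    mask = make_ball_mask((28, 28, 28), (14, 14, 14), 10.0)
    return LabelVolume(mask.astype(np.int32))
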