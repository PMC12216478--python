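import numpy as np
import pytest

from dermpipe.image import RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_rgb():
    """Factory for random 8-bit RGB images of a given shape."""

    def make(h=64, w=64, seed=0):
        g = np.random.default_rng(seed)
        return RasterImage(g.integers(0, 256, (h, w, 3), dtype=np.uint8))

    return make
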