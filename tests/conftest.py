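import numpy as np
import pytest

from viscomplexity import ImageRecipe, gen_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_gray():
    """Uniform mid-gray RGB image."""
    return np.full((32, 32, 3), 128, dtype=np.uint8)


@pytest.fixture
def halves():
    """Left half black, right half white."""
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    img[:, 32:] = 255
    return img


@pytest.fixture
def mosaic():
    """A 16-tile, 8-colour mosaic without noise."""
    return gen_image(ImageRecipe(seed=7, tiles=16, palette=8))


@pytest.fixture
def random_rgb(rng):
    return rng.integers(0, 256, size=(48, 48, 3)).astype(np.uint8)
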