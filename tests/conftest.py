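import numpy as np
import pytest

from exmquant import NoiseParams


@pytest.fixture
def mild_noise():
    """Shot + read noise at a level where thresholding still separates
    structure cleanly from background."""
    return NoiseParams(gaussian_sd=0.02, poisson_scale=200.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blob_mask(rng, shape=(64, 64), n_seeds=6, dilations=3):
    """An irregular connected-ish binary mask for moment/closing properties."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    rows = rng.integers(8, shape[0] - 8, n_seeds)
    cols = rng.integers(8, shape[1] - 8, n_seeds)
    mask[rows, cols] = True
    for _ in range(dilations):
        mask = ndimage.binary_dilation(mask)
    return mask
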