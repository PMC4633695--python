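import numpy as np
import pytest

from nlmpca import NLMParams, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_volume(rng):
    """Seeded 8x8x8 random volume in [0, 100]."""
    return Volume(rng.uniform(0.0, 100.0, (8, 8, 8)))


@pytest.fixture
def tiny_nlm_params():
    """Small radii suitable for 8^3 volumes; explicit h for exactness."""
    return NLMParams(search_radius=2, patch_radius=1, block_stride=1, h=30.0)
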