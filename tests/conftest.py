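import numpy as np
import pytest
from hypothesis import settings

from tonguescreen.fixtures import (
    SyntheticImageParams, make_image_dataset, make_feature_dataset,
)

# reproducible property tests
settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_image_set():
    """20 synthetic 64x64 tongue images with strong class effects."""
    params = SyntheticImageParams(height=64, width=64, color_effect=40.0,
                                  texture_effect=25.0, noise_sd=8.0, seed=7)
    return make_image_dataset(20, params)


@pytest.fixture(scope="session")
def one_image(small_image_set):
    ds = small_image_set
    return ds.images[0], ds.masks[0]


@pytest.fixture(scope="session")
def feature_set():
    """500 x 20 Gaussian features, 3 informative at delta=2."""
    return make_feature_dataset(500, 20, 3, 2.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
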