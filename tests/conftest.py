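import numpy as np
import pytest

import rvflkit as rk


@pytest.fixture(scope="session")
def gauss24():
    """Well-separated two-Gaussian feature cloud, 200/class, 24-D."""
    return rk.gen_features(
        rk.FeatureSimConfig(n_per_class=200, dim=24, separation=4.0, seed=11)
    )


@pytest.fixture(scope="session")
def small_features():
    """Tiny 8-D feature matrix for fast fit/predict tests."""
    return rk.gen_features(
        rk.FeatureSimConfig(n_per_class=40, dim=8, separation=3.0, seed=7)
    )


@pytest.fixture(scope="session")
def random_system():
    """Fixed random (B, Y) pair, tall."""
    rng = np.random.default_rng(42)
    return rng.standard_normal((40, 10)), rng.standard_normal((40, 2))
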