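import numpy as np
import pytest

from amenability.synthetic_descriptors import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_synthetic():
    """Modest planted table reused across read-only tests."""
    cfg = SyntheticConfig(n_compounds=600, label_noise=0.05, n_redundant=4,
                          n_quasi_constant=2, n_noise=10, seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def noiseless_synthetic():
    """Rule-generated labels with no flips; the rule is exactly learnable."""
    cfg = SyntheticConfig(n_compounds=2000, label_noise=0.0, n_redundant=0,
                          n_quasi_constant=0, n_noise=0, seed=11)
    return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
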