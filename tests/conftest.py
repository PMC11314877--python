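import numpy as np
import pytest

from spadspec import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def coarse_config():
    """Noise-free generator config on a coarse 5 nm grid (fast)."""
    return SyntheticConfig(step=5.0, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """4 groups x 12 samples on a 5 nm grid with mild noise."""
    cfg = SyntheticConfig(step=5.0, n_per_group=12, noise_sd=0.01, seed=7)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
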