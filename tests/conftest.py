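import numpy as np
import pytest

from gsrank import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Small noiseless additive dataset: marker signal fully determines y."""
    return simulate_dataset(
        SimConfig(n=80, p=40, n_qtl=8, heritability=1.0, seed=11)
    )


@pytest.fixture(scope="session")
def noisy_sim():
    """Moderate-heritability dataset for behavioural (non-exact) checks."""
    return simulate_dataset(
        SimConfig(n=100, p=50, n_qtl=10, heritability=0.5, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
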