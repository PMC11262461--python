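import numpy as np
import pytest

from spatialccc import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small single-cell simulation with a strong planted channel."""
    cfg = SimulationConfig(n_units=80, G=2, dmax=3.0, seed=11, n_noise_genes=2)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
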