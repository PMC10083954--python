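import logging

import numpy as np
import pytest

from parshift.simulate import SimulationConfig, simulate_dataset

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One full study-design dataset, shared across tests (seed fixed)."""
    return simulate_dataset(default_config, seed=11)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced gene panel for fast structural tests; the sample plan and
    population parameters stay at study defaults."""
    return SimulationConfig(n_left=4, n_mid=3, n_right=4, gene_length=600)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
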