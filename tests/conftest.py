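import numpy as np
import pytest

from raregain import simulate


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: 600 cells, 300 genes, 12 planted SRCC."""
    return simulate.SimulationConfig(
        n_cells=600,
        n_genes=300,
        rare_fraction=0.02,
        n_reference=150,
        n_dormancy_genes=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate.generate_counts(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One instance of the default study conditions (20k cells, 0.1% SRCC)."""
    return simulate.generate_counts(simulate.SimulationConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
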