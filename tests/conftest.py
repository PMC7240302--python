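import numpy as np
import pytest

from t4t5.config import SimulationConfig


@pytest.fixture
def config() -> SimulationConfig:
    """Small-but-complete simulation config for fast tests."""
    return SimulationConfig(n_neurons_per_subtype=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_expression():
    """One default-config expression matrix shared across tests."""
    from t4t5 import synthetic as syn

    return syn.generate_expression(SimulationConfig(), seed=0)


def random_histograms(rng, n, n_bins=12):
    """Random normalised polar histograms (Dirichlet masses)."""
    from t4t5.morphometry import PolarHistogram

    edges = np.linspace(0.0, 360.0, n_bins + 1)
    masses = rng.dirichlet(np.ones(n_bins), size=n)
    return [PolarHistogram(m, edges, n_vectors=100) for m in masses]
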