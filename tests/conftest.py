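import numpy as np
import pytest

from acidflux.synthetic_data import SimConfig, simulate_counts, simulate_network


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete two-regime synthetic dataset with planted truth."""
    cfg = SimConfig(n_genes=400, de_fraction=0.1, lfc_range=(2.0, 4.0), seed=7)
    counts, design, truth = simulate_counts(cfg)
    network, truth = simulate_network(cfg, truth)
    return cfg, counts, design, truth, network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
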