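import numpy as np
import pytest

from fcentropy import SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_adj():
    """Chain K-A-B-L: edges KA, AB, BL."""
    adj = np.zeros((4, 4), dtype=np.uint8)
    for i, j in [(0, 1), (1, 2), (2, 3)]:
        adj[i, j] = adj[j, i] = 1
    return adj


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small synthetic cohort shared across tests (20-region, short series)."""
    cfg = SimulationConfig(
        n_regions=20, n_timepoints=60, n_controls=5, n_early=3, n_late=3
    )
    return generate_cohort(cfg, seed=42)
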