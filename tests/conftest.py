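import numpy as np
import pandas as pd
import pytest

from plastevo.simulate import SimulationConfig, generate_expression


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """10-gene x 4-sample matrix with known CPM structure."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(10, 4)),
        index=[f"g{i}" for i in range(10)],
        columns=["s1", "s2", "s3", "s4"],
    )
    return counts


@pytest.fixture(scope="session")
def small_sim():
    """One small full-design simulation reused across tests."""
    cfg = SimulationConfig(n_genes=300, replicates_per_group=3, seed=42)
    counts, samples, truth = generate_expression(cfg)
    return cfg, counts, samples, truth
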