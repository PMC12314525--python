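import numpy as np
import pytest

from clonearch import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vertex_dataset():
    """K=4 distinct archetype rows, each repeated 50 times, no noise."""
    gen = np.random.default_rng(5)
    Z = gen.normal(0.0, 2.0, size=(4, 10))
    X = Z[np.repeat(np.arange(4), 50)]
    return X, Z


@pytest.fixture(scope="session")
def archetype_sim():
    """Noiseless Dirichlet archetype mixture with known ground truth."""
    cfg = synthetic.ArchetypeSimConfig(
        n_cells=500, n_features=10, n_archetypes=4,
        dirichlet_alpha=0.3, noise_sd=0.0, seed=3,
    )
    X, A, Z = synthetic.simulate_archetype_expression(cfg)
    return X, A, Z


@pytest.fixture(scope="session")
def drift_tables():
    """Small neutral-drift count table reused across dynamics tests."""
    cfg = synthetic.LineageSimConfig(
        n_lineages=200, birth_rate=0.5, death_rate=0.5, duration=20,
        initial_cells=20, seed=7,
    )
    truth = synthetic.simulate_lineage_truth(cfg)
    table = synthetic.simulate_barcode_drift(cfg, truth=truth)
    return cfg, truth, table
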