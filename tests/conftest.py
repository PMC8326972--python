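import numpy as np
import pytest

import cellfate as cf


@pytest.fixture(scope="session")
def three_cluster_data():
    """The 3 x 100 cells, 200 genes, fold-4 recovery fixture."""
    params = cf.SimulationParams(seed=11)
    expr, truth, markers = cf.simulate_mixed_population(params)
    return expr, truth, markers


@pytest.fixture(scope="session")
def three_cluster_norm(three_cluster_data):
    expr, truth, markers = three_cluster_data
    genes = cf.select_variable_genes(expr, 60)
    return cf.normalize_log_cpm(expr), truth, markers, genes


@pytest.fixture(scope="session")
def transition_pair():
    """Two-dataset fixture at rho = 0.5 with 60-cell clusters."""
    params = cf.SimulationParams(n_cells_per_cluster=(60, 60, 60, 60),
                                 sharing_rho=0.5, seed=7)
    (e1, a1), (e2, a2), truth = cf.simulate_transition_pair(params)
    genes = cf.select_variable_genes(e1, 60)
    return (cf.normalize_log_cpm(e1), a1), (cf.normalize_log_cpm(e2), a2), \
        truth, genes


@pytest.fixture
def rng():
    return np.random.default_rng(42)
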