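import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_z(rng):
    """Fisher-Z matrix of a 20-node modular subject (4 modules of 5)."""
    import braingraph as bg

    cov = bg.make_module_covariance(bg.default_partition(20, 4), 0.6, 0.1)
    ts = bg.simulate_subject_timeseries(cov, 400, rng)
    return bg.fisher_z(bg.correlation_matrix(ts))


def adjacency_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return adj


@pytest.fixture
def path4():
    return adjacency_from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def star5():
    return adjacency_from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def complete4():
    adj = np.ones((4, 4), dtype=bool)
    np.fill_diagonal(adj, False)
    return adj
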