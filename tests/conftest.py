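import logging

import numpy as np
import pytest

from ftdnet.cohort import CohortConfig

# mixed-model fits on small fixtures legitimately drop degenerate random
# factors; silence the warnings so test output stays readable
logging.getLogger("ftdnet").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort_config():
    """Desk-scale cohort: small groups, few regions, short series."""
    return CohortConfig(
        n_gene_negative=12,
        n_carrier=10,
        n_ftd=8,
        n_regions=36,
        n_timepoints=96,
        n_sites=2,
        community_size=6,
        seed=11,
    )


def random_connected_weighted_graph(rng, n_max=30):
    """A random connected weighted graph as a dense symmetric matrix."""
    from ftdnet.graphs import BrainGraph

    n = int(rng.integers(5, n_max + 1))
    density = float(rng.uniform(0.15, 0.6))
    while True:
        w = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        m = max(n - 1, int(round(density * len(iu))))
        pick = rng.choice(len(iu), size=m, replace=False)
        w[iu[pick], ju[pick]] = rng.uniform(0.05, 1.0, size=m)
        w += w.T
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        if connected_components(csr_matrix(w), directed=False)[0] == 1:
            return BrainGraph(subject_id="rand", weights=w, edge_density=density)


def floyd_warshall_oracle(weights):
    """Independent brute-force all-pairs shortest paths with length 1/weight."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = d[i, k] + d[k, j]
                if via < d[i, j]:
                    d[i, j] = via
    return d
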