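"""Shared fixtures and independent dense/brute-force oracles.

The oracles deliberately avoid the package's factored sparse code paths:
dense operators are assembled with plain numpy from the incidence matrix,
and hypergraph distances come from a hyperedge-frontier breadth-first
search over explicit member sets.
"""

import numpy as np
import pytest

from hyperwave import build_incidence
from hyperwave.synthetic import generate_dataset, random_hypergraph


# --- independent oracles ----------------------------------------------------

def dense_diffusion(H: np.ndarray) -> np.ndarray:
    """Dense P_H = H D_E^{-1} H^T D_V^{-1} straight from the definition."""
    H = np.asarray(H, dtype=float)
    de = H.sum(axis=0)
    dv = H.sum(axis=1)
    return H @ np.diag(1.0 / de) @ H.T @ np.diag(1.0 / dv)


def bfs_hyperedge_distances(edges: list[set], n: int, source: int) -> np.ndarray:
    """Brute-force hyperedge-hop distances by frontier expansion."""
    dist = np.full(n, np.inf)
    dist[source] = 0
    frontier = {source}
    d = 0
    while frontier:
        d += 1
        nxt: set[int] = set()
        for e in edges:
            if e & frontier:
                nxt |= e
        nxt = {v for v in nxt if not np.isfinite(dist[v])}
        for v in nxt:
            dist[v] = d
        frontier = nxt
    return dist


def random_hyperedge_list(rng: np.random.Generator, n: int, m: int) -> list[set]:
    """Random hyperedge sets covering every vertex (sizes 1..4)."""
    edges = [set(rng.choice(n, size=rng.integers(1, 5), replace=False).tolist()) for _ in range(m)]
    covered = set().union(*edges)
    for v in set(range(n)) - covered:
        edges[rng.integers(m)].add(int(v))
    return edges


# --- fixtures ---------------------------------------------------------------

@pytest.fixture
def triangle_hg():
    """Two hyperedges {v0,v1,v2}, {v1,v2}: the worked 3-vertex example."""
    return build_incidence([{0, 1, 2}, {1, 2}], 3)


@pytest.fixture
def path_hg():
    """Path v0-v1-v2 encoded as the 2-uniform hypergraph {v0,v1},{v1,v2}."""
    return build_incidence([{0, 1}, {1, 2}], 3)


@pytest.fixture(scope="session")
def random_battery():
    """Seeded battery of Bernoulli random hypergraphs for operator algebra."""
    return [random_hypergraph(25, 30, 0.15, seed=s) for s in range(10)]


@pytest.fixture(scope="session")
def small_tissue():
    """A small synthetic tissue shared across feature/pipeline tests."""
    return generate_dataset(
        n_cells=400, n_genes=30, n_regions=3, n_types=6,
        effect_size=3.0, noise=0.1, seed=7,
    )
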