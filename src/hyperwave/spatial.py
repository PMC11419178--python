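"""Cell-cell graphs from spatial coordinates and k-hop hypergraph lifting.

The cell graph ``G_0`` places one vertex per cell.  The default edge rule
connects cells whose Voronoi regions touch, computed through the Delaunay
triangulation (the planar dual of the Voronoi diagram); a symmetrized
k-nearest-neighbor graph is the alternative.  Long boundary edges — artifacts
of unbounded Voronoi regions around hull cells — can be pruned with
``max_edge_length``.

The k-hop lifting turns ``G_0`` into a hypergraph with one hyperedge per
cell: hyperedge ``j`` is the closed k-hop neighborhood
``{w : d(j, w) <= k}`` of seed cell ``j`` (the seed is always a member since
``d(j, j) = 0``).  Identical neighborhoods are deliberately NOT deduplicated
so that hyperedge index = seed cell index = niche index throughout the
pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from sklearn.neighbors import kneighbors_graph

from .hypergraph import Hypergraph, diffusion_operator

__all__ = ["CellGraph", "build_cell_graph", "khop_lift", "receptive_field_check"]


@dataclass
class CellGraph:
    """Planar cell-cell graph with coordinates.

    ``adjacency`` is sparse, symmetric, binary, zero-diagonal.  Disconnected
    graphs are allowed; ``component_labels`` flags the components and the
    lifting handles them independently.
    """

    coordinates: np.ndarray
    adjacency: sp.csr_array
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        A = sp.csr_array(self.adjacency).astype(np.float64)
        A.setdiag(0)
        A.eliminate_zeros()
        if (A != A.T).nnz:
            raise ValueError("adjacency must be symmetric")
        self.adjacency = A

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def component_labels(self) -> np.ndarray:
        _, labels = connected_components(self.adjacency, directed=False)
        return labels

    @property
    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency, directed=False)
        return n_comp == 1

    def edge_list(self) -> np.ndarray:
        """Undirected edges as a sorted (n_edges, 2) index array."""
        coo = sp.coo_array(sp.triu(self.adjacency))
        edges = np.column_stack([coo.coords[0], coo.coords[1]])
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        return edges[order]


def _delaunay_edges(coords: np.ndarray) -> set[tuple[int, int]]:
    tri = Delaunay(coords)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    return edges


def build_cell_graph(
    coordinates: np.ndarray,
    method: str = "voronoi_adjacency",
    max_edge_length: float | None = None,
    k_neighbors: int | None = None,
    duplicate_policy: str = "jitter",
    jitter_seed: int = 0,
) -> CellGraph:
    """Build the cell-cell graph ``G_0`` from 2-D coordinates.

    ``voronoi_adjacency`` and ``delaunay`` both use Delaunay triangulation
    (Voronoi-region adjacency is its dual); ``knn`` builds a symmetrized
    k-nearest-neighbor graph.  Exact duplicate points are jittered by a
    relative 1e-9 perturbation (``duplicate_policy="jitter"``, seeded) or
    rejected (``"error"``).  Degenerate (e.g. collinear) configurations fall
    back to a knn graph with a warning.
    """
    coords = np.asarray(coordinates, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coordinates must be an n x 2 array")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if method not in ("voronoi_adjacency", "delaunay", "knn"):
        raise ValueError(f"unknown method {method!r}")

    _, first_index, counts = np.unique(
        coords, axis=0, return_index=True, return_counts=True
    )
    if np.any(counts > 1):
        if duplicate_policy == "error":
            raise ValueError("duplicate coordinates present")
        if duplicate_policy != "jitter":
            raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
        rng = np.random.default_rng(jitter_seed)
        span = max(np.ptp(coords[:, 0]), np.ptp(coords[:, 1]), 1.0)
        dup_mask = np.ones(n, dtype=bool)
        dup_mask[first_index] = False
        coords = coords.copy()
        coords[dup_mask] += rng.normal(scale=1e-9 * span, size=(dup_mask.sum(), 2))

    params: dict = {
        "max_edge_length": max_edge_length,
        "k_neighbors": k_neighbors,
    }

    if method == "knn":
        if k_neighbors is None:
            k_neighbors = min(6, n - 1)
        if k_neighbors >= n:
            raise ValueError("k_neighbors must be smaller than the number of cells")
        A = kneighbors_graph(coords, n_neighbors=k_neighbors, mode="connectivity")
        A = sp.csr_array(A)
        A = ((A + A.T) > 0).astype(np.float64)
        params["k_neighbors"] = k_neighbors
    else:
        try:
            edge_set = _delaunay_edges(coords)
        except QhullError:
            warnings.warn(
                "Delaunay triangulation failed (degenerate point configuration); "
                "falling back to a symmetrized knn graph",
                RuntimeWarning,
                stacklevel=2,
            )
            fallback_k = k_neighbors if k_neighbors is not None else min(2, n - 1)
            return build_cell_graph(
                coords, method="knn", k_neighbors=fallback_k,
                max_edge_length=max_edge_length, duplicate_policy="jitter",
                jitter_seed=jitter_seed,
            )
        if max_edge_length is not None:
            edge_set = {
                (i, j)
                for (i, j) in edge_set
                if np.linalg.norm(coords[i] - coords[j]) <= max_edge_length
            }
        if edge_set:
            rows, cols = np.array(sorted(edge_set)).T
        else:
            rows = cols = np.array([], dtype=int)
        A = sp.csr_array(
            (np.ones(2 * rows.size), (np.r_[rows, cols], np.r_[cols, rows])),
            shape=(n, n),
        )
        A = (A > 0).astype(np.float64)

    return CellGraph(coordinates=coords, adjacency=sp.csr_array(A), method=method, params=params)


def khop_lift(g: CellGraph, k: int = 3) -> Hypergraph:
    """Lift a cell graph to the cellular-niche hypergraph.

    Hyperedge ``j`` is the closed k-hop neighborhood of cell ``j`` on
    ``G_0``; there are exactly ``n`` hyperedges and duplicates are
    preserved, keeping the identity seed-to-niche mapping.  Isolated cells
    yield singleton hyperedges.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = g.n_cells
    A = (g.adjacency > 0).astype(np.float64)
    reach = sp.csr_array(sp.eye_array(n, format="csr"))
    closed = sp.csr_array(A + sp.eye_array(n, format="csr"))
    for _ in range(k):
        reach = closed @ reach
        reach.data[:] = 1.0  # binarize to keep fill under control
    # reach is symmetric; column j (== row j) is the closed k-neighborhood
    # of seed j, so reach itself is the n x n incidence matrix with m = n.
    return Hypergraph(
        sp.csr_array(reach),
        vertex_ids=np.arange(n),
        edge_ids=np.arange(n),
    )


def receptive_field_check(
    g0: CellGraph, k: int, d: int, seed_vertex: int
) -> np.ndarray:
    """Support of ``P_H^d delta_seed`` on the k-hop lifted hypergraph.

    Returns the sorted vertex indices with strictly positive mass after
    ``d`` diffusion steps from ``seed_vertex``.  Each step of hypergraph
    diffusion moves between two members of one hyperedge; both lie within
    ``k`` hops of that hyperedge's seed, so a single step covers at most
    ``2k`` hops on ``G_0`` and after ``d`` steps the support is guaranteed
    to lie within graph distance ``2 * k * d`` of the seed.  The nominal
    receptive field of order ``k * d`` is an empirical observation on
    regular geometries, not a hard bound.  Zero steps return the seed alone.
    """
    if d < 0:
        raise ValueError("d must be nonnegative")
    if seed_vertex < 0 or seed_vertex >= g0.n_cells:
        raise ValueError("seed_vertex out of range")
    hg = khop_lift(g0, k)
    op = diffusion_operator(hg, dense_threshold=0)
    delta = np.zeros(g0.n_cells)
    delta[seed_vertex] = 1.0
    mass = op.apply(delta, steps=d)
    return np.flatnonzero(mass > 0)
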