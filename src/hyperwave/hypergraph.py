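"""Incidence-based hypergraphs and the random-walk diffusion operator.

A hypergraph on ``n`` vertices with ``m`` hyperedges is stored through its
sparse ``n x m`` binary incidence matrix ``H`` (``H[i, j] = 1`` iff vertex
``i`` belongs to hyperedge ``j``).  The central object is the hypergraph
diffusion operator

    ``P_H = H D_E^{-1} H^T D_V^{-1}``

where ``D_V`` and ``D_E`` are the diagonal vertex- and hyperedge-degree
matrices.  ``P_H`` is the transition matrix of the two-step random walk
vertex -> incident hyperedge (uniform) -> member vertex (uniform); it is
column-stochastic, its spectrum lies in ``[0, 1]``, and when every hyperedge
has exactly two vertices it reduces to the lazy random walk
``(I + A_V D_V^{-1}) / 2`` on the underlying graph.

``P_H`` arises as the top-left block of the square of the random-walk matrix
of the bipartite (star) expansion of the hypergraph; the bottom-right block
is the diffusion operator of the dual hypergraph (incidence ``H^T``).  Large
operators are never densified: they are applied signal-by-signal through the
factored sparse form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "Hypergraph",
    "BipartiteExpansion",
    "DiffusionOperator",
    "build_incidence",
    "bipartite_expansion",
    "diffusion_operator",
    "apply_operator",
    "dual_hypergraph",
    "hypergraph_distance",
]

#: Largest n + m for which a dense realization of an operator is permitted.
#: Dense forms exist only for oracles and small-instance checks; the
#: production path is the factored sparse matvec.
DEFAULT_DENSE_THRESHOLD = 2000


def _as_binary_csr(incidence) -> sp.csr_array:
    """Coerce an incidence-like input to a canonical binary CSR array."""
    if sp.issparse(incidence):
        H = sp.csr_array(incidence)
    else:
        H = sp.csr_array(np.asarray(incidence))
    H = H.astype(np.float64)
    H.eliminate_zeros()
    if H.nnz and not np.all(H.data == 1.0):
        raise ValueError("incidence entries must be 0 or 1 (unweighted hypergraph)")
    H.sum_duplicates()
    return H


@dataclass
class Hypergraph:
    """An unweighted hypergraph stored by its sparse incidence matrix.

    Attributes
    ----------
    incidence
        ``n x m`` binary CSR array ``H``.
    vertex_degrees
        Row sums of ``H``; number of hyperedges containing each vertex.
    edge_degrees
        Column sums of ``H``; cardinality of each hyperedge.
    vertex_ids, edge_ids
        Optional external identifiers (defaults: integer ranges).  The
        k-hop lifting of a cell graph keeps hyperedge ``j`` aligned with
        seed cell ``j`` through ``edge_ids``.
    """

    incidence: sp.csr_array
    vertex_ids: np.ndarray | None = None
    edge_ids: np.ndarray | None = None
    vertex_degrees: np.ndarray = field(init=False)
    edge_degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.incidence = _as_binary_csr(self.incidence)
        H = self.incidence
        self.vertex_degrees = np.asarray(H.sum(axis=1)).ravel().astype(np.int64)
        self.edge_degrees = np.asarray(H.sum(axis=0)).ravel().astype(np.int64)
        if np.any(self.edge_degrees == 0):
            raise ValueError("empty hyperedge (zero column in incidence matrix)")
        if np.any(self.vertex_degrees == 0):
            raise ValueError(
                "vertex belongs to no hyperedge; pass repair_isolated=True to "
                "build_incidence / from_incidence to add singleton hyperedges"
            )
        if self.vertex_ids is not None:
            self.vertex_ids = np.asarray(self.vertex_ids)
            if self.vertex_ids.shape[0] != self.n_vertices:
                raise ValueError("vertex_ids length mismatch")
        if self.edge_ids is not None:
            self.edge_ids = np.asarray(self.edge_ids)
            if self.edge_ids.shape[0] != self.n_hyperedges:
                raise ValueError("edge_ids length mismatch")

    @property
    def n_vertices(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_hyperedges(self) -> int:
        return self.incidence.shape[1]

    @classmethod
    def from_incidence(
        cls,
        incidence,
        *,
        vertex_ids=None,
        edge_ids=None,
        repair_isolated: bool = False,
    ) -> "Hypergraph":
        """Build from a (sparse or dense) binary incidence matrix.

        With ``repair_isolated=True``, every vertex with zero degree receives
        a singleton hyperedge ``{v}`` appended after the given columns, which
        keeps ``D_V`` invertible without touching existing hyperedges.
        """
        H = _as_binary_csr(incidence)
        if repair_isolated:
            deg = np.asarray(H.sum(axis=1)).ravel()
            isolated = np.flatnonzero(deg == 0)
            if isolated.size:
                n = H.shape[0]
                extra = sp.csr_array(
                    (np.ones(isolated.size), (isolated, np.arange(isolated.size))),
                    shape=(n, isolated.size),
                )
                H = sp.csr_array(sp.hstack([H, extra]))
                if edge_ids is not None:
                    edge_ids = np.concatenate(
                        [np.asarray(edge_ids), np.asarray([f"singleton_{v}" for v in isolated])]
                    )
        return cls(H, vertex_ids=vertex_ids, edge_ids=edge_ids)

    @classmethod
    def from_hyperedges(
        cls,
        hyperedges,
        n_vertices: int,
        *,
        vertex_ids=None,
        edge_ids=None,
        repair_isolated: bool = False,
    ) -> "Hypergraph":
        """Build from a list of vertex-index collections (one per hyperedge)."""
        hyperedges = list(hyperedges)
        rows: list[int] = []
        cols: list[int] = []
        for j, edge in enumerate(hyperedges):
            members = sorted(set(int(v) for v in edge))
            if not members:
                raise ValueError(f"hyperedge {j} is empty")
            for v in members:
                if v < 0 or v >= n_vertices:
                    raise ValueError(
                        f"vertex id {v} of hyperedge {j} out of range [0, {n_vertices})"
                    )
            rows.extend(members)
            cols.extend([j] * len(members))
        H = sp.csr_array(
            (np.ones(len(rows)), (rows, cols)),
            shape=(n_vertices, len(hyperedges)),
        )
        return cls.from_incidence(
            H, vertex_ids=vertex_ids, edge_ids=edge_ids, repair_isolated=repair_isolated
        )

    def hyperedge_members(self, j: int) -> np.ndarray:
        """Sorted vertex indices of hyperedge ``j``."""
        col = self.incidence[:, [j]].tocoo()
        return np.sort(col.coords[0])

    def dual(self) -> "Hypergraph":
        """Dual hypergraph: vertices and hyperedges interchanged (H* = H^T)."""
        return Hypergraph(
            sp.csr_array(self.incidence.T),
            vertex_ids=self.edge_ids,
            edge_ids=self.vertex_ids,
        )


@dataclass
class BipartiteExpansion:
    """Bipartite (star) expansion of a hypergraph.

    The expanded graph has vertex set V ∪ E with an edge (v, e) whenever
    v ∈ e, adjacency ``[[0, H], [H^T, 0]]`` and degree vector
    ``(d_V, d_E)``.  The symmetrically normalized Laplacian of this graph,
    available through :meth:`normalized_laplacian`, underpins the spectral
    analysis of the diffusion operator and is used by tests as a dense
    oracle.
    """

    adjacency: sp.csr_array
    degrees: np.ndarray
    vertex_block_size: int

    @property
    def n_total(self) -> int:
        return self.adjacency.shape[0]

    def walk_matrix(self) -> sp.csr_array:
        """Column-stochastic random-walk matrix ``P~ = A~ D~^{-1}``."""
        inv_deg = 1.0 / self.degrees
        return sp.csr_array(self.adjacency @ sp.diags_array(inv_deg))

    def normalized_laplacian(self) -> np.ndarray:
        """Dense ``L~_N = I - D~^{-1/2} A~ D~^{-1/2}`` (small instances only)."""
        if self.n_total > DEFAULT_DENSE_THRESHOLD:
            raise ValueError("dense Laplacian requested for a large expansion")
        d = 1.0 / np.sqrt(self.degrees)
        A = self.adjacency.toarray()
        return np.eye(self.n_total) - d[:, None] * A * d[None, :]


class DiffusionOperator:
    """Factored hypergraph diffusion operator ``P_H = H D_E^{-1} H^T D_V^{-1}``.

    The operator is applied by four sparse steps per diffusion step
    (scale by ``D_V^{-1}``, lift with ``H^T``, scale by ``D_E^{-1}``, push
    down with ``H``); a dense realization is only produced on demand for
    instances with ``n + m`` at most ``dense_threshold``.

    ``matvec_count`` counts the number of single-column diffusion steps
    performed (one step applied to ``c`` columns adds ``c``), which is the
    quantity the linear-in-scale complexity contract of the wavelet
    transform is stated in.
    """

    def __init__(self, hypergraph: Hypergraph, dense_threshold: int = DEFAULT_DENSE_THRESHOLD):
        if np.any(hypergraph.vertex_degrees < 1) or np.any(hypergraph.edge_degrees < 1):
            raise ValueError("diffusion operator requires all degrees >= 1")
        self.hypergraph = hypergraph
        self.dense_threshold = int(dense_threshold)
        self._H = sp.csr_array(hypergraph.incidence)
        self._Ht = sp.csr_array(hypergraph.incidence.T)
        self._inv_dv = 1.0 / hypergraph.vertex_degrees.astype(np.float64)
        self._inv_de = 1.0 / hypergraph.edge_degrees.astype(np.float64)
        self.matvec_count = 0
        self._dense: np.ndarray | None = None

    @property
    def n(self) -> int:
        """Dimension of the vertex space the operator acts on."""
        return self._H.shape[0]

    def reset_matvec_count(self) -> None:
        self.matvec_count = 0

    def step(self, signals: np.ndarray) -> np.ndarray:
        """One application of ``P_H`` to an ``n x c`` signal matrix."""
        x = np.asarray(signals, dtype=np.float64)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[:, None]
        if x.shape[0] != self.n:
            raise ValueError(f"signal has {x.shape[0]} rows, operator expects {self.n}")
        y = x * self._inv_dv[:, None]
        y = self._Ht @ y
        y *= self._inv_de[:, None]
        y = self._H @ y
        self.matvec_count += x.shape[1]
        return y[:, 0] if squeeze else y

    def apply(self, signals: np.ndarray, steps: int = 1) -> np.ndarray:
        """Compute ``P_H^steps @ signals`` by iterated sparse matvecs."""
        if steps < 0:
            raise ValueError("steps must be nonnegative")
        x = np.asarray(signals, dtype=np.float64)
        if x.shape[0] != self.n:
            raise ValueError(f"signal has {x.shape[0]} rows, operator expects {self.n}")
        out = x.copy()
        for _ in range(steps):
            out = self.step(out)
        return out

    def to_dense(self) -> np.ndarray:
        """Dense realization of ``P_H`` (oracle/testing path only)."""
        total = self.n + self._H.shape[1]
        if total > self.dense_threshold:
            raise ValueError(
                f"dense realization refused: n + m = {total} exceeds "
                f"threshold {self.dense_threshold}"
            )
        if self._dense is None:
            H = self._H.toarray()
            self._dense = (H * self._inv_de[None, :]) @ H.T * self._inv_dv[None, :]
        return self._dense


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def build_incidence(
    hyperedges,
    n_vertices: int,
    *,
    repair_isolated: bool = False,
    vertex_ids=None,
    edge_ids=None,
) -> Hypergraph:
    """Build a :class:`Hypergraph` from a list of vertex-id sets.

    Raises on empty hyperedges, out-of-range ids, and (unless
    ``repair_isolated``) vertices belonging to no hyperedge.
    """
    return Hypergraph.from_hyperedges(
        list(hyperedges),
        n_vertices,
        vertex_ids=vertex_ids,
        edge_ids=edge_ids,
        repair_isolated=repair_isolated,
    )


def bipartite_expansion(g: Hypergraph) -> BipartiteExpansion:
    """Star expansion with adjacency ``[[0, H], [H^T, 0]]``."""
    H = g.incidence
    n = H.shape[0]
    adjacency = sp.csr_array(sp.block_array([[None, H], [H.T, None]], format="csr"))
    degrees = np.concatenate([g.vertex_degrees, g.edge_degrees]).astype(np.float64)
    return BipartiteExpansion(adjacency=adjacency, degrees=degrees, vertex_block_size=n)


def diffusion_operator(
    g: Hypergraph, dense_threshold: int = DEFAULT_DENSE_THRESHOLD
) -> DiffusionOperator:
    """Factored diffusion operator ``P_H`` of a hypergraph."""
    return DiffusionOperator(g, dense_threshold=dense_threshold)


def apply_operator(op: DiffusionOperator, signals: np.ndarray, steps: int) -> np.ndarray:
    """``P_H^steps @ signals`` through the factored sparse form."""
    return op.apply(signals, steps=steps)


def dual_hypergraph(g: Hypergraph) -> Hypergraph:
    """Hypergraph with vertices and hyperedges interchanged (``H* = H^T``)."""
    return g.dual()


def hypergraph_distance(g: Hypergraph, source: int) -> np.ndarray:
    """Minimum number of hyperedges on a path from ``source`` to each vertex.

    Computed as half the breadth-first distance on the bipartite expansion
    (every vertex-to-vertex path alternates vertex/hyperedge, so bipartite
    path lengths between vertices are even).  Unreachable vertices get
    ``np.inf``; the returned array is float for that reason.
    """
    n = g.n_vertices
    if source < 0 or source >= n:
        raise ValueError(f"source {source} out of range [0, {n})")
    exp = bipartite_expansion(g)
    d = shortest_path(exp.adjacency, method="D", unweighted=True, indices=source)
    return np.asarray(d[:n]) / 2.0


def hypergraph_components(g: Hypergraph) -> np.ndarray:
    """Connected-component label per vertex, via the bipartite expansion."""
    exp = bipartite_expansion(g)
    _, labels = connected_components(exp.adjacency, directed=False)
    return labels[: g.n_vertices]
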