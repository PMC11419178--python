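"""Hyperedge (cellular-niche) features and wavelet niche representations.

Starting from normalized, log-transformed expression, four feature families
are computed per hyperedge and concatenated into the niche feature matrix
``z`` (one row per hyperedge):

1. mean transformed expression of each selected gene over member cells;
2. Pearson correlation between pairs of selected genes within the hyperedge;
3. Pearson correlation between each selected gene and one diffusion step of
   the full expression signal, within the hyperedge;
4. member counts per cell-type category at three label granularities
   (cell type, subclass, supertype).

The niche representation applies the diffusion wavelet bank on the DUAL
hypergraph (whose vertices are the hyperedges of the original) to the
columns of ``z`` and flattens the coefficients, yielding one multiscale
vector per niche.  Row ``i`` of every matrix corresponds to the niche seeded
at cell ``i``.

Correlation degeneracies are mapped to 0 by convention: hyperedges with
fewer than three members, and gene pairs where either gene is constant
within the hyperedge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import SpectralClustering

from .hypergraph import DiffusionOperator, Hypergraph, diffusion_operator, dual_hypergraph
from .wavelets import ScaleSequence, flatten_coefficients, wavelet_transform

__all__ = [
    "ExpressionMatrix",
    "CellLabels",
    "NicheFeatureMatrix",
    "NicheRepresentation",
    "transform_counts",
    "select_variable_genes",
    "mean_expression_features",
    "gene_pair_correlation_features",
    "diffusion_correlation_features",
    "celltype_count_features",
    "assemble_features",
    "niche_representations",
    "cluster_niches",
]

#: Variance below this (on log-scale values) counts as constant within an edge.
_VAR_EPS = 1e-12
#: Minimum hyperedge degree for a within-edge correlation to be defined.
_MIN_CORR_DEG = 3


@dataclass
class ExpressionMatrix:
    """Raw counts plus their library-size-normalized, log1p-transformed form."""

    counts: np.ndarray
    transformed: np.ndarray
    gene_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.transformed.shape[0]

    @property
    def n_genes(self) -> int:
        return self.transformed.shape[1]


@dataclass
class CellLabels:
    """Per-cell categorical labels at three granularities.

    The granularities are not assumed to be nested.  Category vocabularies
    are fixed (sorted unique values) at construction; transforming data with
    unseen categories against a fixed vocabulary is an error.
    """

    cell_type: np.ndarray
    subclass: np.ndarray
    supertype: np.ndarray
    vocabularies: dict = field(init=False)

    def __post_init__(self) -> None:
        self.cell_type = np.asarray(self.cell_type)
        self.subclass = np.asarray(self.subclass)
        self.supertype = np.asarray(self.supertype)
        n = self.cell_type.shape[0]
        if self.subclass.shape[0] != n or self.supertype.shape[0] != n:
            raise ValueError("label vectors must have equal length")
        for name, arr in self.items():
            if pd.isna(arr).any():
                raise ValueError(f"missing values in {name} labels")
        self.vocabularies = {
            name: np.unique(arr) for name, arr in self.items()
        }

    def items(self):
        return [
            ("cell_type", self.cell_type),
            ("subclass", self.subclass),
            ("supertype", self.supertype),
        ]

    def __len__(self) -> int:
        return self.cell_type.shape[0]


def transform_counts(counts, target_sum: float = 1e4, gene_ids=None) -> ExpressionMatrix:
    """Library-size normalization to ``target_sum`` per cell, then log1p.

    All-zero cells stay zero.  This is the standard single-cell count
    transform and the starting point for all downstream features.
    """
    C = np.asarray(counts.toarray() if sp.issparse(counts) else counts, dtype=np.float64)
    if C.ndim != 2:
        raise ValueError("counts must be a 2-D cells x genes matrix")
    if not np.all(np.isfinite(C)):
        raise ValueError("counts must be finite")
    if np.any(C < 0):
        raise ValueError("counts must be nonnegative")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    lib = C.sum(axis=1)
    scale = np.divide(target_sum, lib, out=np.zeros_like(lib), where=lib > 0)
    transformed = np.log1p(C * scale[:, None])
    if gene_ids is None:
        gene_ids = np.array([f"gene_{k}" for k in range(C.shape[1])])
    else:
        gene_ids = np.asarray(gene_ids)
        if gene_ids.shape[0] != C.shape[1]:
            raise ValueError("gene_ids length mismatch")
    return ExpressionMatrix(counts=C, transformed=transformed, gene_ids=gene_ids)


def select_variable_genes(expr: ExpressionMatrix, n_top: int = 30) -> np.ndarray:
    """Indices of the ``n_top`` most variable genes (transformed variance).

    Ties break toward the lower gene index, so the selection is stable under
    permutations of cells.
    """
    var = expr.transformed.var(axis=0)
    order = np.lexsort((np.arange(var.size), -var))
    return np.sort(order[: min(n_top, var.size)])


def _check_alignment(expr: ExpressionMatrix, g: Hypergraph) -> None:
    if expr.n_cells != g.n_vertices:
        raise ValueError(
            f"expression has {expr.n_cells} cells but hypergraph has "
            f"{g.n_vertices} vertices"
        )


def mean_expression_features(
    expr: ExpressionMatrix, g: Hypergraph, gene_subset
) -> np.ndarray:
    """Mean transformed expression per hyperedge: ``m x |G|``."""
    _check_alignment(expr, g)
    gene_subset = np.asarray(gene_subset)
    if gene_subset.size == 0:
        raise ValueError("gene subset must be non-empty")
    X = expr.transformed[:, gene_subset]
    sums = g.incidence.T @ X
    return sums / g.edge_degrees[:, None]


def _edge_sums(g: Hypergraph, X: np.ndarray) -> np.ndarray:
    """Per-hyperedge column sums of a cells x c matrix."""
    return g.incidence.T @ X


def _edgewise_correlation(
    g: Hypergraph, X: np.ndarray, Y: np.ndarray
) -> np.ndarray:
    """Pearson correlation of paired columns of X and Y within each hyperedge.

    Vectorized through per-edge sufficient statistics (sums, squares, cross
    products).  Entries where the hyperedge has fewer than three members or
    either column is constant within the edge are 0.
    """
    deg = g.edge_degrees.astype(np.float64)[:, None]
    Sx, Sy = _edge_sums(g, X), _edge_sums(g, Y)
    Sxx, Syy = _edge_sums(g, X * X), _edge_sums(g, Y * Y)
    Sxy = _edge_sums(g, X * Y)
    var_x = Sxx / deg - (Sx / deg) ** 2
    var_y = Syy / deg - (Sy / deg) ** 2
    cov = Sxy / deg - (Sx / deg) * (Sy / deg)
    valid = (deg >= _MIN_CORR_DEG) & (var_x > _VAR_EPS) & (var_y > _VAR_EPS)
    denom = np.sqrt(np.where(valid, var_x * var_y, 1.0))
    corr = np.where(valid, cov / denom, 0.0)
    return np.clip(corr, -1.0, 1.0)


def gene_pair_correlation_features(
    expr: ExpressionMatrix, g: Hypergraph, gene_subset
) -> np.ndarray:
    """Within-hyperedge Pearson correlation for every gene pair.

    Pairs are enumerated in fixed upper-triangle order over the subset:
    (g0,g1), (g0,g2), ..., (g1,g2), ...  Output is
    ``m x (|G| * (|G|-1) / 2)``.
    """
    _check_alignment(expr, g)
    gene_subset = np.asarray(gene_subset)
    if gene_subset.size == 0:
        raise ValueError("gene subset must be non-empty")
    X = expr.transformed[:, gene_subset]
    ia, ib = np.triu_indices(gene_subset.size, k=1)
    return _edgewise_correlation(g, X[:, ia], X[:, ib])


def diffusion_correlation_features(
    expr: ExpressionMatrix, g: Hypergraph, op: DiffusionOperator, gene_subset
) -> np.ndarray:
    """Correlation between each gene and one diffusion step of it, per edge.

    The diffusion is applied once, globally, to the transformed expression of
    the selected genes; correlations are then taken within each hyperedge
    between the original and diffused columns.  The operator defaults to the
    hypergraph diffusion operator of the lifted hypergraph, but any operator
    on the same vertex set (e.g. the lazy walk of the cell graph encoded as a
    2-uniform hypergraph) can be passed.
    """
    _check_alignment(expr, g)
    if op.n != expr.n_cells:
        raise ValueError("operator dimension does not match the number of cells")
    gene_subset = np.asarray(gene_subset)
    if gene_subset.size == 0:
        raise ValueError("gene subset must be non-empty")
    X = expr.transformed[:, gene_subset]
    D = op.apply(X, steps=1)
    return _edgewise_correlation(g, X, D)


def celltype_count_features(
    labels: CellLabels, g: Hypergraph, vocabularies: dict | None = None
) -> tuple[np.ndarray, list[str]]:
    """Per-hyperedge member counts for each category at each granularity.

    Category order is the sorted vocabulary, fixed at label construction (or
    passed explicitly when transforming new data against a fitted
    vocabulary); an unseen category is an error.  Per granularity, each row
    sums to the hyperedge degree.  Returns the ``m x (T1+T2+T3)`` matrix and
    its column names.
    """
    if len(labels) != g.n_vertices:
        raise ValueError("labels length does not match the number of vertices")
    vocabularies = vocabularies or labels.vocabularies
    blocks: list[np.ndarray] = []
    names: list[str] = []
    Ht = g.incidence.T
    for granularity, values in labels.items():
        vocab = np.asarray(vocabularies[granularity])
        codes_map = {cat: i for i, cat in enumerate(vocab)}
        unknown = set(np.unique(values)) - set(vocab)
        if unknown:
            raise ValueError(
                f"unknown {granularity} categories {sorted(map(str, unknown))} "
                "not in the fitted vocabulary"
            )
        codes = np.array([codes_map[v] for v in values])
        onehot = sp.csr_array(
            (np.ones(len(codes)), (np.arange(len(codes)), codes)),
            shape=(len(codes), vocab.size),
        )
        blocks.append((Ht @ onehot).toarray())
        names.extend(f"{granularity}:{cat}" for cat in vocab)
    return np.hstack(blocks), names


@dataclass
class NicheFeatureMatrix:
    """The hyperedge feature matrix ``z`` with its column schema.

    ``blocks`` maps block name -> (start, stop) column slice; row ``i``
    belongs to the niche seeded at cell ``i``.  Standardization (z-score per
    column over hyperedges) is recorded so that the raw matrix can be
    recovered.
    """

    values: np.ndarray
    column_names: list[str]
    blocks: dict[str, tuple[int, int]]
    gene_subset: np.ndarray | None = None
    edge_ids: np.ndarray | None = None
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_stds: np.ndarray | None = None

    @property
    def n_hyperedges(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        index = self.edge_ids if self.edge_ids is not None else np.arange(self.n_hyperedges)
        return pd.DataFrame(self.values, columns=self.column_names, index=index)


def assemble_features(
    blocks: list[tuple[str, np.ndarray, list[str]]],
    *,
    standardize: bool = True,
    gene_subset=None,
    edge_ids=None,
) -> NicheFeatureMatrix:
    """Concatenate feature blocks into ``z`` in schema order.

    ``blocks`` is an ordered list of (name, m x w matrix, column names).
    With ``standardize=True`` every column is z-scored across hyperedges
    after assembly (constant columns become 0); this puts count-scale and
    correlation-scale features on a common scale before the wavelet
    transform.
    """
    if not blocks:
        raise ValueError("need at least one feature block")
    m = blocks[0][1].shape[0]
    mats, names, schema = [], [], {}
    start = 0
    for name, mat, cols in blocks:
        mat = np.asarray(mat, dtype=np.float64)
        if mat.ndim != 2 or mat.shape[0] != m:
            raise ValueError(f"block {name!r} row count mismatch")
        if len(cols) != mat.shape[1]:
            raise ValueError(f"block {name!r} column-name count mismatch")
        mats.append(mat)
        names.extend(cols)
        schema[name] = (start, start + mat.shape[1])
        start += mat.shape[1]
    values = np.hstack(mats)
    means = stds = None
    if standardize:
        means = values.mean(axis=0)
        stds = values.std(axis=0)
        safe = np.where(stds > _VAR_EPS, stds, 1.0)
        values = (values - means) / safe
        values[:, stds <= _VAR_EPS] = 0.0
    return NicheFeatureMatrix(
        values=values,
        column_names=names,
        blocks=schema,
        gene_subset=None if gene_subset is None else np.asarray(gene_subset),
        edge_ids=None if edge_ids is None else np.asarray(edge_ids),
        standardized=standardize,
        column_means=means,
        column_stds=stds,
    )


@dataclass
class NicheRepresentation:
    """Flattened wavelet coefficients ``W_J z`` of the niche features.

    One row per niche (hyperedge of the original hypergraph, i.e. vertex of
    the dual); width ``p * (J + 1)``.
    """

    values: np.ndarray
    column_names: list[str]
    scales: ScaleSequence
    flatten_mode: str
    edge_ids: np.ndarray | None = None

    @property
    def n_niches(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        index = self.edge_ids if self.edge_ids is not None else np.arange(self.n_niches)
        return pd.DataFrame(self.values, columns=self.column_names, index=index)


def niche_representations(
    z: NicheFeatureMatrix,
    g: Hypergraph,
    scales: ScaleSequence,
    flatten_mode: str = "concatenate",
) -> NicheRepresentation:
    """Wavelet niche representations ``W_J z`` on the dual hypergraph.

    Builds the dual of ``g`` (vertices = hyperedges of ``g``), its diffusion
    operator, runs the wavelet transform on the columns of ``z`` and flattens
    the coefficients in filter order.  Row order (niche = seed cell) is
    preserved.
    """
    if z.n_hyperedges != g.n_hyperedges:
        raise ValueError("feature rows must match the number of hyperedges")
    dual = dual_hypergraph(g)
    op = diffusion_operator(dual)
    wc = wavelet_transform(op, z.values, scales)
    flat = flatten_coefficients(wc, mode=flatten_mode)
    labels = [f"psi_{i}" for i in range(scales.J)] + ["phi"]
    names = [f"{lab}:{col}" for lab in labels for col in z.column_names]
    return NicheRepresentation(
        values=flat,
        column_names=names,
        scales=scales,
        flatten_mode=flatten_mode,
        edge_ids=z.edge_ids,
    )


def cluster_niches(
    rep, n_clusters: int, seed: int = 0, n_neighbors: int = 15
) -> np.ndarray:
    """Spectral clustering of niche representations.

    Uses a k-nearest-neighbor affinity over representation rows; the result
    is deterministic for a fixed seed.  Accepts a
    :class:`NicheRepresentation` or a plain matrix.
    """
    X = rep.values if isinstance(rep, NicheRepresentation) else np.asarray(rep)
    m = X.shape[0]
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > m:
        raise ValueError(f"n_clusters={n_clusters} exceeds the number of niches {m}")
    if n_clusters == 1:
        return np.zeros(m, dtype=int)
    model = SpectralClustering(
        n_clusters=n_clusters,
        affinity="nearest_neighbors",
        n_neighbors=min(n_neighbors, m - 1),
        assign_labels="kmeans",
        random_state=seed,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        # kNN affinity graphs are frequently non-symmetric pre-symmetrization;
        # sklearn warns and symmetrizes, which is exactly what we want.
        _warnings.filterwarnings("ignore", message=".*not fully connected.*")
        return model.fit_predict(X)
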