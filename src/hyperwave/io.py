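"""Text-format I/O: delimited tables, hypergraph exchange, AnnData bridge.

All on-disk formats are plain text: CSV tables for coordinates, counts and
labels; a two-column (hyperedge_id, vertex_id) incidence list and
MatrixMarket for hypergraphs; edge lists for cell graphs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .features import CellLabels
from .hypergraph import Hypergraph
from .spatial import CellGraph
from .synthetic import SyntheticDataset

__all__ = [
    "read_coordinates",
    "write_coordinates",
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "write_hypergraph_incidence_list",
    "read_hypergraph_incidence_list",
    "write_hypergraph_mtx",
    "read_hypergraph_mtx",
    "write_edge_list",
    "write_dataset",
    "read_dataset",
    "from_anndata",
]


# --- tabular inputs --------------------------------------------------------

def read_coordinates(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (cell_id, x, y) CSV; returns (coordinates, cell_ids)."""
    df = pd.read_csv(path)
    for col in ("cell_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinates table missing column {col!r}")
    return df[["x", "y"]].to_numpy(dtype=np.float64), df["cell_id"].to_numpy()


def write_coordinates(path, coordinates: np.ndarray, cell_ids=None) -> None:
    coords = np.asarray(coordinates)
    if cell_ids is None:
        cell_ids = np.arange(coords.shape[0])
    pd.DataFrame(
        {"cell_id": cell_ids, "x": coords[:, 0], "y": coords[:, 1]}
    ).to_csv(path, index=False)


def read_counts(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a cells x genes CSV (index = cell_id, header = gene ids)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), df.index.to_numpy(), df.columns.to_numpy()


def write_counts(path, counts: np.ndarray, cell_ids=None, gene_ids=None) -> None:
    counts = np.asarray(counts)
    if cell_ids is None:
        cell_ids = np.arange(counts.shape[0])
    if gene_ids is None:
        gene_ids = [f"gene_{k}" for k in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=pd.Index(cell_ids, name="cell_id"), columns=gene_ids)
    df.to_csv(path)


def read_labels(path) -> tuple[CellLabels, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("cell_id", "cell_type", "subclass", "supertype"):
        if col not in df.columns:
            raise ValueError(f"labels table missing column {col!r}")
    labels = CellLabels(
        cell_type=df["cell_type"].to_numpy(),
        subclass=df["subclass"].to_numpy(),
        supertype=df["supertype"].to_numpy(),
    )
    return labels, df["cell_id"].to_numpy()


def write_labels(path, labels: CellLabels, cell_ids=None, extra: dict | None = None) -> None:
    if cell_ids is None:
        cell_ids = np.arange(len(labels))
    data = {
        "cell_id": cell_ids,
        "cell_type": labels.cell_type,
        "subclass": labels.subclass,
        "supertype": labels.supertype,
    }
    if extra:
        data.update(extra)
    pd.DataFrame(data).to_csv(path, index=False)


# --- hypergraph exchange ---------------------------------------------------

def write_hypergraph_incidence_list(path, g: Hypergraph) -> None:
    """Two-column TSV (hyperedge_id, vertex_id), one row per incidence."""
    coo = sp.coo_array(g.incidence)
    df = pd.DataFrame({"hyperedge_id": coo.coords[1], "vertex_id": coo.coords[0]})
    df.sort_values(["hyperedge_id", "vertex_id"]).to_csv(path, sep="\t", index=False)


def read_hypergraph_incidence_list(path, n_vertices: int | None = None) -> Hypergraph:
    df = pd.read_csv(path, sep="\t")
    edges = df["hyperedge_id"].to_numpy()
    verts = df["vertex_id"].to_numpy()
    n = int(verts.max()) + 1 if n_vertices is None else n_vertices
    m = int(edges.max()) + 1
    H = sp.csr_array((np.ones(len(df)), (verts, edges)), shape=(n, m))
    return Hypergraph(H)


def write_hypergraph_mtx(path, g: Hypergraph) -> None:
    mmwrite(str(path), sp.coo_matrix(g.incidence))


def read_hypergraph_mtx(path) -> Hypergraph:
    return Hypergraph(sp.csr_array(mmread(str(path))))


def write_edge_list(path, g: CellGraph) -> None:
    pd.DataFrame(g.edge_list(), columns=["source", "target"]).to_csv(
        path, sep="\t", index=False
    )


# --- dataset bundles -------------------------------------------------------

def write_dataset(out_dir, dataset: SyntheticDataset) -> None:
    """Write a synthetic tissue as the CSV bundle the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cell_ids = np.arange(dataset.n_cells)
    write_coordinates(out / "coords.csv", dataset.coordinates, cell_ids)
    write_counts(out / "counts.csv", dataset.counts, cell_ids)
    write_labels(
        out / "labels.csv",
        dataset.labels,
        cell_ids,
        extra={"niche_region": dataset.niche_region, "stage": dataset.stage},
    )


def read_dataset(in_dir) -> tuple[np.ndarray, np.ndarray, CellLabels, np.ndarray]:
    """Read (coordinates, counts, labels, cell_ids) from a CSV bundle."""
    in_dir = Path(in_dir)
    coords, coord_ids = read_coordinates(in_dir / "coords.csv")
    counts, count_ids, _ = read_counts(in_dir / "counts.csv")
    labels, label_ids = read_labels(in_dir / "labels.csv")
    if not (np.array_equal(coord_ids, count_ids) and np.array_equal(coord_ids, label_ids)):
        raise ValueError("cell_id columns disagree across the bundle")
    return coords, counts, labels, coord_ids


def from_anndata(adata, coord_key: str = "spatial") -> tuple[np.ndarray, np.ndarray, CellLabels]:
    """Extract (coordinates, counts, labels) from an AnnData container.

    Expects 2-D coordinates in ``adata.obsm[coord_key]`` and obs columns
    ``cell_type``, ``subclass``, ``supertype``.
    """
    coords = np.asarray(adata.obsm[coord_key], dtype=np.float64)
    X = adata.X
    counts = X.toarray() if sp.issparse(X) else np.asarray(X)
    labels = CellLabels(
        cell_type=adata.obs["cell_type"].to_numpy(),
        subclass=adata.obs["subclass"].to_numpy(),
        supertype=adata.obs["supertype"].to_numpy(),
    )
    return coords, counts, labels
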