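"""Expression-matrix container, file I/O, normalization and partition utilities.

Cells are rows and genes are columns everywhere in memory. Matrix-Market
triplet files on disk follow the 10x convention (genes as rows) and are
transposed at the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "ExpressionMatrix",
    "ClusterAssignment",
    "load_expression",
    "save_expression",
    "load_cluster_labels",
    "save_cluster_labels",
    "load_gene_list",
    "normalize_log_cpm",
    "select_variable_genes",
    "align_gene_universe",
    "adjusted_rand_index",
]


class FormatError(ValueError):
    """Raised when an input file is structurally inconsistent."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A cells x genes matrix of non-negative expression values.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_genes)
        Raw counts or normalized expression; never negative.
    cell_ids, gene_ids : list of str
        Unique row / column names.
    normalized : bool
        Whether ``values`` has already been normalized (log-CPM or a
        user-supplied scheme). Raw counts carry ``False``.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", list(map(str, self.cell_ids)))
        object.__setattr__(self, "gene_ids", list(map(str, self.gene_ids)))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if np.any(values < 0):
            raise ValueError("expression values must be non-negative")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Column positions of ``genes``; raises KeyError on unknown genes."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"unknown genes: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            self.values[:, idx], self.cell_ids, [self.gene_ids[i] for i in idx],
            normalized=self.normalized,
        )

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise KeyError(f"unknown cells: {missing[:5]}")
        idx = np.array([lookup[c] for c in cells], dtype=int)
        return ExpressionMatrix(
            self.values[idx], [self.cell_ids[i] for i in idx], self.gene_ids,
            normalized=self.normalized,
        )


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-cell cluster labels (the categorical response of the classifier)."""

    cell_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_ids", list(map(str, self.cell_ids)))
        object.__setattr__(self, "labels", np.asarray(self.labels))
        if len(self.cell_ids) != len(self.labels):
            raise ValueError("cell_ids and labels differ in length")
        if len(self.labels) == 0:
            raise ValueError("empty cluster assignment")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")

    @property
    def clusters(self) -> list:
        """Distinct labels in order of first appearance."""
        seen: dict = {}
        for lab in self.labels.tolist():
            seen.setdefault(lab, None)
        return list(seen)

    def members(self, cluster) -> list[str]:
        return [c for c, lab in zip(self.cell_ids, self.labels) if lab == cluster]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_one_column(path: str) -> list[str]:
    with open(path) as fh:
        out = [line.strip().split("\t")[0] for line in fh if line.strip()]
    return out


def load_expression(path: str, format: str = "mtx_triplet", *,
                    normalized: bool = False) -> ExpressionMatrix:
    """Load an expression matrix from disk.

    ``mtx_triplet`` expects ``<path>.mtx`` (genes x cells, Matrix-Market
    coordinate) plus sidecars ``<path>.genes.tsv`` and ``<path>.cells.tsv``;
    ``path`` is the shared prefix. ``dense_csv`` expects a single CSV with a
    header row of gene names and the first column holding cell names.
    """
    if format == "mtx_triplet":
        mtx = path + ".mtx"
        genes_f = path + ".genes.tsv"
        cells_f = path + ".cells.tsv"
        for f in (mtx, genes_f, cells_f):
            if not os.path.exists(f):
                raise FileNotFoundError(f)
        mat = scio.mmread(mtx)
        genes = _read_one_column(genes_f)
        cells = _read_one_column(cells_f)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix is {mat.shape} but sidecars list "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        values = np.asarray(
            mat.toarray() if sparse.issparse(mat) else mat, dtype=float
        ).T  # genes x cells on disk -> cells x genes in memory
        return ExpressionMatrix(values, cells, genes, normalized=normalized)
    if format == "dense_csv":
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=float), list(df.index.astype(str)),
            list(df.columns.astype(str)), normalized=normalized,
        )
    raise ValueError(f"unknown format {format!r}")


def save_expression(expr: ExpressionMatrix, path: str,
                    format: str = "mtx_triplet") -> None:
    """Write an expression matrix in either supported on-disk format."""
    if format == "mtx_triplet":
        scio.mmwrite(path + ".mtx", sparse.coo_matrix(expr.values.T))
        for fname, ids in ((path + ".genes.tsv", expr.gene_ids),
                           (path + ".cells.tsv", expr.cell_ids)):
            with open(fname, "w") as fh:
                fh.write("\n".join(ids) + "\n")
    elif format == "dense_csv":
        pd.DataFrame(expr.values, index=expr.cell_ids,
                     columns=expr.gene_ids).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_cluster_labels(path: str) -> ClusterAssignment:
    """Read a 2-column TSV (cell_id, label), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"],
                     dtype={"cell_id": str})
    return ClusterAssignment(list(df["cell_id"]), df["label"].to_numpy())


def save_cluster_labels(assignment: ClusterAssignment, path: str) -> None:
    pd.DataFrame({"cell_id": assignment.cell_ids,
                  "label": assignment.labels}).to_csv(
        path, sep="\t", header=False, index=False)


def load_gene_list(path: str) -> list[str]:
    """One gene id per line; order preserved, duplicates rejected."""
    genes = _read_one_column(path)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in gene list")
    return genes


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def normalize_log_cpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million per cell followed by log2(x + 1).

    Each row is scaled to sum to 1e6 before the log transform. A default
    normalization so the pipeline runs end-to-end on raw counts; users with
    their own normalization should load with ``normalized=True`` instead.
    """
    if expr.normalized:
        raise ValueError("matrix is already normalized")
    totals = expr.values.sum(axis=1)
    bad = np.flatnonzero(totals == 0)
    if bad.size:
        raise ValueError(
            f"cell(s) with zero total count: {[expr.cell_ids[i] for i in bad[:5]]}"
        )
    cpm = expr.values / totals[:, None] * 1e6
    return replace(expr, values=np.log2(cpm + 1.0), normalized=True)


def select_variable_genes(expr: ExpressionMatrix, n_top: int) -> list[str]:
    """The ``n_top`` genes of largest variance across cells.

    Ties break lexicographically on gene id so the selection is deterministic.
    If ``n_top`` exceeds the gene count, all genes are returned (still in
    variance order).
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    variances = expr.values.var(axis=0, ddof=1) if expr.n_cells > 1 \
        else np.zeros(expr.n_genes)
    order = sorted(range(expr.n_genes),
                   key=lambda j: (-variances[j], expr.gene_ids[j]))
    return [expr.gene_ids[j] for j in order[:n_top]]


def align_gene_universe(a: ExpressionMatrix, b: ExpressionMatrix,
                        genes: Sequence[str]):
    """Restrict both matrices to ``genes ∩ a.gene_ids ∩ b.gene_ids``.

    Both outputs carry the surviving genes in the same column order (the order
    of ``genes``), so a model trained on one can score cells of the other.
    """
    a_set, b_set = set(a.gene_ids), set(b.gene_ids)
    shared = [g for g in genes if g in a_set and g in b_set]
    if not shared:
        raise ValueError("no genes shared between the two matrices and the list")
    return a.subset_genes(shared), b.subset_genes(shared), shared


# ---------------------------------------------------------------------------
# Partition agreement
# ---------------------------------------------------------------------------

def adjusted_rand_index(p1: ClusterAssignment, p2: ClusterAssignment) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    Both assignments must cover the identical cell set; ``p2`` is reordered to
    ``p1``'s cell order before comparison. Returns 1.0 for identical
    partitions up to label renaming; symmetric in its arguments.
    """
    if set(p1.cell_ids) != set(p2.cell_ids):
        raise ValueError("cluster assignments cover different cell sets")
    pos = {c: i for i, c in enumerate(p2.cell_ids)}
    l2 = np.asarray([p2.labels[pos[c]] for c in p1.cell_ids])
    _, a = np.unique(np.asarray(p1.labels, dtype=str), return_inverse=True)
    _, b = np.unique(np.asarray(l2, dtype=str), return_inverse=True)
    return float(adjusted_rand_score(a, b))
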