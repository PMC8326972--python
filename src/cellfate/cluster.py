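"""Stability-selected hierarchical clustering of cells.

The procedure builds one Ward dendrogram over all cells in the original
expression space (no dimensionality reduction), extracts flat clusterings at
a grid of evenly spaced tree heights ("windows"), scores each partition by
how many consecutive windows reproduce it (its stability), and then selects
the number of clusters by bootstrap bagging: the stored distance matrix is
subsampled with replacement many times, each subsample is re-clustered by
pure indexing into the stored distances, and the per-bag optimal cluster
counts are voted on. The final partition is the most stable window of the
original tree with the voted cluster count.

Ward linkage follows Wishart's formulation: the Lance–Williams recurrence
with Ward coefficients applied to squared Euclidean distances, so merge
heights are reported on the squared-distance scale. Only relative heights
matter for cutting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .data import ClusterAssignment, ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "WindowScan",
    "BagSample",
    "BaggingResult",
    "StabilityClustering",
    "distance_matrix",
    "ward_dendrogram",
    "window_scan",
    "bag_once",
    "score_cluster",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric zero-diagonal Euclidean distances between cells."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.cell_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix size does not match cell_ids")
        if np.any(v < 0):
            raise ValueError("negative distances")
        if not np.array_equal(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history over cells.

    ``merges`` has one row per merge: (left node, right node, height,
    merged size), with leaves numbered 0..n-1 and internal nodes n, n+1, ...
    in merge order; heights are Ward dissimilarities on the squared-distance
    scale and are non-decreasing.
    """

    merges: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.merges, dtype=float)
        object.__setattr__(self, "merges", m)
        n = len(self.leaf_ids)
        if m.shape != (n - 1, 4):
            raise ValueError("expected n-1 merges of 4 fields")
        if np.any(np.diff(m[:, 2]) < -1e-9 * max(1.0, abs(m[-1, 2]))):
            raise ValueError("merge heights are not non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def max_height(self) -> float:
        return float(self.merges[-1, 2])

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaf_ids[i] for i in range(n)}
        for step, (li, ri, h, _) in enumerate(self.merges):
            li, ri = int(li), int(ri)
            bl_l = h - height[li]
            bl_r = h - height[ri]
            node[n + step] = f"({node[li]}:{bl_l:g},{node[ri]}:{bl_r:g})"
            height[n + step] = float(h)
        return node[n + self.n_leaves - 2] + ";"


@dataclass(frozen=True)
class WindowScan:
    """Flat clusterings at evenly spaced cut heights and their stability.

    Window 1 sits at the lowest cut (highest resolution); the last window
    cuts at the final merge height. The stability of a partition is the
    length of the longest consecutive window run reproducing it, divided by
    the number of windows.
    """

    n_windows: int
    cut_heights: np.ndarray
    partitions: list[np.ndarray]
    cluster_counts: np.ndarray
    stabilities: np.ndarray
    optimal_index: int
    stability: float

    @property
    def optimal_partition(self) -> np.ndarray:
        return self.partitions[self.optimal_index]

    @property
    def optimal_k(self) -> int:
        return int(self.cluster_counts[self.optimal_index])


@dataclass(frozen=True)
class BagSample:
    """One bootstrap draw: cell positions and the indexed sub-distance matrix."""

    indices: np.ndarray
    sub_distance: DistanceMatrix


@dataclass(frozen=True)
class BaggingResult:
    """Outcome of the bagging vote and the selected partition."""

    per_bag_k: np.ndarray
    running_mean: np.ndarray
    voted_k: int
    final_partition: ClusterAssignment
    final_stability: float
    fallback_used: bool
    window_scan: WindowScan
    dendrogram: Dendrogram


# ---------------------------------------------------------------------------
# Array-level core
# ---------------------------------------------------------------------------

def _ward_linkage(dist: np.ndarray) -> np.ndarray:
    """Ward merge table with heights on the squared-distance scale.

    scipy's ``ward`` update is the Lance–Williams recurrence on squared
    distances followed by a square root, so squaring its heights recovers
    Wishart's formulation exactly.
    """
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="ward")
    z = z.copy()
    z[:, 2] = z[:, 2] ** 2
    return z


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first cell appearance."""
    out = np.empty(len(labels), dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels.tolist()):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _cut_below(z: np.ndarray, n: int, h: float) -> np.ndarray:
    """Flat clustering grouping leaves connected by merges of height < h."""
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - 1):
        if z[step, 2] >= h:
            break
        a, b = find(int(z[step, 0])), find(int(z[step, 1]))
        root = n + step
        parent[a] = root
        parent[b] = root
    return _canonical(np.array([find(i) for i in range(n)]))


def _window_scan_arrays(z: np.ndarray, n: int, n_windows: int) -> WindowScan:
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    h_max = float(z[-1, 2])
    cut_heights = np.arange(1, n_windows + 1) / n_windows * h_max
    partitions = [_cut_below(z, n, h) for h in cut_heights]
    counts = np.array([p.max() for p in partitions])

    # longest consecutive run per distinct partition
    keys = [p.tobytes() for p in partitions]
    run_len: dict[bytes, int] = {}
    first_win: dict[bytes, int] = {}
    i = 0
    while i < n_windows:
        j = i
        while j + 1 < n_windows and keys[j + 1] == keys[i]:
            j += 1
        length = j - i + 1
        if length > run_len.get(keys[i], 0):
            run_len[keys[i]] = length
        first_win.setdefault(keys[i], i)
        i = j + 1

    # the two trivial partitions (everything merged, nothing merged) are
    # never selected while an informative alternative persists
    candidates = [i for i in range(n_windows) if 1 < counts[i] < n]
    if not candidates:
        candidates = [i for i in range(n_windows) if counts[i] > 1] \
            or list(range(n_windows))
    best = max(
        candidates,
        key=lambda i: (run_len[keys[i]], counts[i], -first_win[keys[i]]),
    )
    best = first_win[keys[best]]
    stabilities = np.array([run_len[k] / n_windows for k in keys])
    return WindowScan(
        n_windows=n_windows,
        cut_heights=cut_heights,
        partitions=partitions,
        cluster_counts=counts,
        stabilities=stabilities,
        optimal_index=best,
        stability=run_len[keys[best]] / n_windows,
    )


def _draw_indices(rng, n: int, m: int, replace: bool) -> np.ndarray:
    if replace:
        return np.sort(rng.integers(0, n, size=m))
    if m > n:
        raise ValueError("cannot subsample more cells than exist without "
                         "replacement")
    return np.sort(rng.choice(n, size=m, replace=False))


def _bag_k(dist: np.ndarray, proportion: float, rng, n_windows: int,
           replace: bool = False) -> int:
    n = dist.shape[0]
    m = int(np.ceil(proportion * n))
    if m < 2:
        raise ValueError("subsample smaller than 2 cells")
    idx = _draw_indices(rng, n, m, replace)
    sub = dist[np.ix_(idx, idx)]
    if not np.any(sub > 0):
        warnings.warn("degenerate subsample: all drawn cells identical")
        return 1
    z = _ward_linkage(sub)
    if z[-1, 2] == 0:  # all merges at height zero
        return 1
    return _window_scan_arrays(z, m, n_windows).optimal_k


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class StabilityClustering(ClusterMixin, BaseEstimator):
    """Bagged Ward clustering with stability-based resolution selection.

    Parameters
    ----------
    n_windows : int, default 40
        Number of evenly spaced cut heights scanned under the dendrogram.
    n_bags : int, default 100
        Bootstrap subsamples voted on for the cluster count.
    proportion : float, default 0.8
        Fraction of cells drawn per bag.
    replace : bool, default False
        Draw bag cells with replacement instead of plain subsampling.
        Retained duplicates act as inflated-weight points under Ward and
        blur the resolution bands, so plain subsampling is the default.
    random_state : int or None
        Seed for the bagging stream; a fixed seed gives bit-identical output.

    Attributes
    ----------
    labels_ : ndarray of shape (n_cells,)
        Selected partition, clusters numbered 1..k in order of appearance.
    voted_k_ : int
        Modal optimal cluster count over the bags (ties to the smaller k).
    per_bag_k_ : ndarray of shape (n_bags,)
        Optimal cluster count of every bag.
    running_mean_ : ndarray
        Cumulative mean of ``per_bag_k_`` (the bagging diagnostic trace).
    stability_ : float
        Stability of the selected partition on the original tree.
    fallback_used_ : bool
        True when no window of the original tree had the voted count and the
        scan optimum was used instead.
    linkage_ : ndarray
        Merge table (left, right, squared-scale height, size).
    window_scan_ : WindowScan
        Full scan of the original tree.
    """

    def __init__(self, n_windows: int = 40, n_bags: int = 100,
                 proportion: float = 0.8, replace: bool = False,
                 random_state: int | None = None):
        self.n_windows = n_windows
        self.n_bags = n_bags
        self.proportion = proportion
        self.replace = replace
        self.random_state = random_state

    def fit(self, X, y=None) -> "StabilityClustering":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 cells")
        dist = squareform(pdist(X, metric="euclidean"))
        return self._fit_from_distances(dist)

    def _fit_from_distances(self, dist: np.ndarray) -> "StabilityClustering":
        n = dist.shape[0]
        self.distances_ = dist
        self.linkage_ = _ward_linkage(dist)
        self.window_scan_ = _window_scan_arrays(self.linkage_, n, self.n_windows)

        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_bags)
        per_bag = np.array([
            _bag_k(dist, self.proportion, np.random.default_rng(s),
                   self.n_windows, replace=self.replace)
            for s in seeds
        ])
        self.per_bag_k_ = per_bag
        self.running_mean_ = np.cumsum(per_bag) / np.arange(1, len(per_bag) + 1)

        values, freq = np.unique(per_bag, return_counts=True)
        self.voted_k_ = int(values[freq == freq.max()].min())

        scan = self.window_scan_
        matching = [i for i in range(scan.n_windows)
                    if scan.cluster_counts[i] == self.voted_k_]
        if matching:
            best = max(matching, key=lambda i: scan.stabilities[i])
            self.labels_ = scan.partitions[best]
            self.stability_ = float(scan.stabilities[best])
            self.fallback_used_ = False
        else:
            warnings.warn(
                f"no window with the voted cluster count {self.voted_k_}; "
                "falling back to the scan optimum")
            self.labels_ = scan.optimal_partition
            self.stability_ = scan.stability
            self.fallback_used_ = True
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# Domain-typed operations
# ---------------------------------------------------------------------------

def distance_matrix(expr: ExpressionMatrix,
                    genes: Sequence[str]) -> DistanceMatrix:
    """Pairwise Euclidean distances over the gene-restricted expression."""
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells")
    sub = expr.subset_genes(genes)
    d = squareform(pdist(sub.values, metric="euclidean"))
    return DistanceMatrix(d, expr.cell_ids)


def ward_dendrogram(d: DistanceMatrix) -> Dendrogram:
    """Ward (Wishart variant) agglomeration of a distance matrix."""
    if len(d.cell_ids) < 2:
        raise ValueError("need at least 2 cells")
    return Dendrogram(_ward_linkage(d.values), d.cell_ids)


def window_scan(tree: Dendrogram, n_windows: int = 40) -> WindowScan:
    """Scan ``n_windows`` evenly spaced cut heights of the dendrogram."""
    return _window_scan_arrays(tree.merges, tree.n_leaves, n_windows)


def bag_once(M: DistanceMatrix, proportion: float, rng,
             n_windows: int = 40, replace: bool = False,
             return_sample: bool = False):
    """One bagging run: subsample cells, re-cluster, return the optimal k.

    The subsample's distances are taken by pure indexing into ``M`` (no
    recomputation), so entries are bit-identical to the parent matrix —
    including exact zeros at duplicate pairs when ``replace`` is True.
    """
    n = len(M.cell_ids)
    m = int(np.ceil(proportion * n))
    if m < 2:
        raise ValueError("subsample smaller than 2 cells")
    idx = _draw_indices(rng, n, m, replace)
    sub = M.values[np.ix_(idx, idx)]
    sample = BagSample(idx, DistanceMatrix(sub, [M.cell_ids[i] for i in idx])) \
        if return_sample else None
    if not np.any(sub > 0):
        warnings.warn("degenerate subsample: all drawn cells identical")
        k = 1
    else:
        z = _ward_linkage(sub)
        k = 1 if z[-1, 2] == 0 else _window_scan_arrays(z, m, n_windows).optimal_k
    return (k, sample) if return_sample else k


def score_cluster(expr: ExpressionMatrix, genes: Sequence[str] | None = None,
                  n_windows: int = 40, n_bags: int = 100,
                  proportion: float = 0.8, replace: bool = False,
                  seed: int | None = None) -> BaggingResult:
    """Full stability-clustering run on an expression matrix.

    Builds the dendrogram once, scans it, votes over ``n_bags`` bootstrap
    re-clusterings of the stored distance matrix, and returns the most stable
    original-tree partition with the voted cluster count.
    """
    genes = list(genes) if genes is not None else list(expr.gene_ids)
    est = StabilityClustering(n_windows=n_windows, n_bags=n_bags,
                              proportion=proportion, replace=replace,
                              random_state=seed)
    est.fit(expr.subset_genes(genes).values)
    return BaggingResult(
        per_bag_k=est.per_bag_k_,
        running_mean=est.running_mean_,
        voted_k=est.voted_k_,
        final_partition=ClusterAssignment(expr.cell_ids, est.labels_),
        final_stability=est.stability_,
        fallback_used=est.fallback_used_,
        window_scan=est.window_scan_,
        dendrogram=Dendrogram(est.linkage_, expr.cell_ids),
    )
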