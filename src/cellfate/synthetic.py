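"""Negative-binomial count simulator with planted clusters.

Emulates droplet-style single-cell counts: per-gene baseline means drawn
log-normal, counts drawn negative-binomial (mean mu, size theta, variance
mu + mu^2/theta), and each cluster carrying a disjoint program of marker
genes whose mean is multiplied by a fold change. A two-dataset mode plants a
related cluster in the second dataset that retains a controllable fraction
of the first cluster's marker program, so directional transition scoring has
a tunable ground truth.

Dropout beyond the NB's own zeros, batch effects and library-size gradients
are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ClusterAssignment, ExpressionMatrix

__all__ = ["SimulationParams", "simulate_mixed_population",
           "simulate_transition_pair"]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the count simulator.

    Defaults give three clusters of 100 cells over 200 genes with 20
    up-regulated markers per cluster at fold change 4. Baseline means
    exp(N(3, 0.5)) sit around 20 counts per gene per cell — the deep
    coverage of full-length (Smart-seq-style) protocols, scaled to a
    200-gene universe — and ``dispersion`` (NB size theta = 10) adds
    moderate overdispersion on top of Poisson sampling. In this regime a
    fold change of 4 yields well-separated clusters, so fold_change acts as
    the separability dial: near 1 there is no recoverable structure.
    """

    n_cells_per_cluster: tuple[int, ...] = (100, 100, 100)
    n_genes: int = 200
    n_markers_per_cluster: int = 20
    fold_change: float = 4.0
    base_mean_log_mu: float = 3.0
    base_mean_log_sigma: float = 0.5
    dispersion: float = 10.0
    sharing_rho: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_cells_per_cluster",
                           tuple(int(n) for n in self.n_cells_per_cluster))
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1 (markers up-regulated)")
        if not 0 <= self.sharing_rho <= 1:
            raise ValueError("sharing_rho must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        k = len(self.n_cells_per_cluster)
        if self.n_markers_per_cluster * k > self.n_genes:
            raise ValueError("marker programs exceed the gene universe")
        if any(n < 1 for n in self.n_cells_per_cluster):
            raise ValueError("each cluster needs at least one cell")

    @property
    def n_clusters(self) -> int:
        return len(self.n_cells_per_cluster)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             theta: float) -> np.ndarray:
    """NB(mean mu, size theta): p = theta / (theta + mu)."""
    return rng.negative_binomial(theta, theta / (theta + mean))


def _baselines(params: SimulationParams, rng: np.random.Generator):
    mu = np.exp(rng.normal(params.base_mean_log_mu,
                           params.base_mean_log_sigma, params.n_genes))
    genes = [f"g{j:04d}" for j in range(params.n_genes)]
    return mu, genes


def _marker_blocks(params: SimulationParams) -> list[np.ndarray]:
    m = params.n_markers_per_cluster
    return [np.arange(c * m, (c + 1) * m) for c in range(params.n_clusters)]


def _draw_cluster(rng, n_cells: int, mu: np.ndarray, markers: np.ndarray,
                  fold: float, theta: float) -> np.ndarray:
    mean = mu.copy()
    mean[markers] *= fold
    return _nb_draw(rng, np.tile(mean, (n_cells, 1)), theta)


def simulate_mixed_population(params: SimulationParams):
    """One mixed population with planted clusters.

    Returns ``(counts, truth, markers)``: an ExpressionMatrix of raw counts,
    the true ClusterAssignment, and a marker table (gene, cluster). Fixed
    seed gives identical output.
    """
    rng = np.random.default_rng(params.seed)
    mu, genes = _baselines(params, rng)
    blocks = _marker_blocks(params)

    chunks, labels, cells = [], [], []
    for c, n_cells in enumerate(params.n_cells_per_cluster):
        chunks.append(_draw_cluster(rng, n_cells, mu, blocks[c],
                                    params.fold_change, params.dispersion))
        labels.extend([c + 1] * n_cells)
        cells.extend(f"c{c + 1}_{i:04d}" for i in range(n_cells))
    counts = np.vstack(chunks).astype(float)

    expr = ExpressionMatrix(counts, cells, genes, normalized=False)
    truth = ClusterAssignment(cells, np.array(labels))
    markers = pd.DataFrame(
        [(genes[j], c + 1) for c, blk in enumerate(blocks) for j in blk],
        columns=["gene", "cluster"])
    return expr, truth, markers


def simulate_transition_pair(params: SimulationParams):
    """Two datasets with a partially shared marker program.

    Dataset 1 holds cluster A, carrying a marker program, and cluster B at
    pure baseline; dataset 2 holds A' and C, where A' keeps a fraction
    ``sharing_rho`` of A's markers (the rest reset to baseline) and C
    carries an independent disjoint program. B is left programless so the
    one-vs-rest classifier for A must rely on positive A-marker evidence
    rather than on the absence of another cluster's program — at
    ``sharing_rho = 0`` the A' cells are then genuine baseline negatives.
    Both datasets share the gene universe and baseline means. The truth
    record lists which directed pairs are related.

    Cluster sizes come from ``n_cells_per_cluster``: entries 0-3 give
    |A|, |B|, |A'|, |C| (a 3-tuple reuses the last entry for C).
    """
    sizes = params.n_cells_per_cluster
    if len(sizes) < 4:
        sizes = tuple(sizes) + (sizes[-1],) * (4 - len(sizes))
    m = params.n_markers_per_cluster
    if 2 * m > params.n_genes:
        raise ValueError("need room for two disjoint marker programs")

    rng = np.random.default_rng(params.seed)
    mu, genes = _baselines(params, rng)
    block_a = np.arange(0, m)
    block_b = np.arange(0)  # B is the baseline cluster
    block_c = np.arange(m, 2 * m)
    n_shared = int(round(params.sharing_rho * m))
    block_a_shared = block_a[:n_shared]

    def build(name, specs):
        chunks, labels, cells = [], [], []
        for cluster, n_cells, markers in specs:
            chunks.append(_draw_cluster(rng, n_cells, mu, markers,
                                        params.fold_change, params.dispersion))
            labels.extend([cluster] * n_cells)
            cells.extend(f"{name}_{cluster}_{i:04d}" for i in range(n_cells))
        expr = ExpressionMatrix(np.vstack(chunks).astype(float), cells, genes,
                                normalized=False)
        return expr, ClusterAssignment(cells, np.array(labels, dtype=object))

    pop1 = build("d1", [("A", sizes[0], block_a), ("B", sizes[1], block_b)])
    pop2 = build("d2", [("Ap", sizes[2], block_a_shared),
                        ("C", sizes[3], block_c)])
    truth = {
        "related_pairs": [("A", "Ap")],
        "sharing_rho": params.sharing_rho,
        "markers": {
            "A": [genes[j] for j in block_a],
            "B": [genes[j] for j in block_b],
            "Ap": [genes[j] for j in block_a_shared],
            "C": [genes[j] for j in block_c],
        },
    }
    return pop1, pop2, truth
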