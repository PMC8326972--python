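"""Ward dendrogram, window scan and bagging against independent oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import cellfate as cf
from cellfate.cluster import _window_scan_arrays


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def naive_ward(dist):
    """Straight-from-the-recurrence O(n^3) Ward agglomeration.

    Works on squared input distances, picks the globally closest active pair
    at every step (ties to the smallest node indices), and updates
    dissimilarities with the Lance-Williams Ward coefficients. Returns a
    list of (leaf-set, leaf-set, height) merge records.
    """
    n = dist.shape[0]
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j] ** 2
    size = {i: 1 for i in range(n)}
    leaves = {i: frozenset([i]) for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = min(
            ((d[(min(i, j), max(i, j))], i, j)
             for i in active for j in active if i < j),
            key=lambda t: (t[0], t[1], t[2]))
        h, i, j = best
        ni, nj = size[i], size[j]
        new = next_id
        next_id += 1
        for k in active - {i, j}:
            nk = size[k]
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            dij = d[(i, j)]
            d[(k, new)] = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) \
                / (ni + nj + nk)
        merges.append((leaves[i], leaves[j], h))
        leaves[new] = leaves[i] | leaves[j]
        size[new] = ni + nj
        active -= {i, j}
        active.add(new)
    return merges


def dendrogram_leaf_merges(tree):
    """Merge records of a Dendrogram as (leaf-set, leaf-set, height)."""
    n = tree.n_leaves
    leaves = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (li, ri, h, _) in enumerate(tree.merges):
        li, ri = int(li), int(ri)
        out.append((leaves[li], leaves[ri], float(h)))
        leaves[n + step] = leaves[li] | leaves[ri]
    return out


def brute_force_distances(X):
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
    return out


def _expr_from(X):
    return cf.ExpressionMatrix(
        np.abs(X), [f"c{i}" for i in range(X.shape[0])],
        [f"g{j}" for j in range(X.shape[1])])


# ---------------------------------------------------------------------------
# distance_matrix
# ---------------------------------------------------------------------------

class TestDistanceMatrix:
    def test_three_four_five_triangle(self):
        expr = cf.ExpressionMatrix(np.array([[0., 0.], [3., 4.]]),
                                   ["a", "b"], ["g1", "g2"])
        d = cf.distance_matrix(expr, ["g1", "g2"])
        assert d.values[0, 1] == pytest.approx(5.0)
        assert d.values[0, 0] == 0

    def test_duplicate_cells_distance_zero(self):
        expr = cf.ExpressionMatrix(np.array([[1., 2.], [1., 2.], [0., 0.]]),
                                   ["a", "b", "c"], ["g1", "g2"])
        d = cf.distance_matrix(expr, ["g1", "g2"])
        assert d.values[0, 1] == 0.0

    def test_matches_brute_force(self, rng):
        X = rng.poisson(6, size=(10, 6)).astype(float)
        d = cf.distance_matrix(_expr_from(X), [f"g{j}" for j in range(6)])
        np.testing.assert_allclose(d.values, brute_force_distances(X),
                                   atol=1e-12)

    def test_single_cell_raises(self):
        expr = cf.ExpressionMatrix(np.ones((1, 2)), ["a"], ["g1", "g2"])
        with pytest.raises(ValueError):
            cf.distance_matrix(expr, ["g1"])

    def test_unknown_gene_raises(self):
        expr = cf.ExpressionMatrix(np.ones((2, 2)), ["a", "b"], ["g1", "g2"])
        with pytest.raises(KeyError):
            cf.distance_matrix(expr, ["nope"])


# ---------------------------------------------------------------------------
# ward_dendrogram
# ---------------------------------------------------------------------------

class TestWardDendrogram:
    def test_two_points_height_is_squared_distance(self):
        d = cf.DistanceMatrix(np.array([[0., 3.], [3., 0.]]), ["a", "b"])
        tree = cf.ward_dendrogram(d)
        assert tree.merges[0, 2] == pytest.approx(9.0)

    def test_three_identical_points_merge_at_zero(self):
        d = cf.DistanceMatrix(np.zeros((3, 3)), ["a", "b", "c"])
        tree = cf.ward_dendrogram(d)
        np.testing.assert_array_equal(tree.merges[:, 2], 0)

    def test_fixed_five_point_configuration(self, rng):
        X = rng.normal(size=(5, 3))
        dist = squareform(pdist(X))
        tree = cf.ward_dendrogram(
            cf.DistanceMatrix(dist, [f"c{i}" for i in range(5)]))
        got = dendrogram_leaf_merges(tree)
        expected = naive_ward(dist)
        for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
            assert {ga, gb} == {ea, eb}
            assert gh == pytest.approx(eh, rel=1e-9)

    @pytest.mark.parametrize("n", [4, 7, 12])
    @pytest.mark.parametrize("trial", range(4))
    def test_matches_naive_recurrence_oracle(self, n, trial):
        rng = np.random.default_rng(1000 * n + trial)
        X = rng.normal(size=(n, 4))
        dist = squareform(pdist(X))
        tree = cf.ward_dendrogram(
            cf.DistanceMatrix(dist, [f"c{i}" for i in range(n)]))
        got = dendrogram_leaf_merges(tree)
        expected = naive_ward(dist)
        assert len(got) == n - 1
        for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
            assert {ga, gb} == {ea, eb}
            assert gh == pytest.approx(eh, rel=1e-9)

    def test_heights_non_decreasing_on_random_inputs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 5))
            tree = cf.ward_dendrogram(cf.DistanceMatrix(
                squareform(pdist(X)), [f"c{i}" for i in range(20)]))
            assert np.all(np.diff(tree.merges[:, 2]) >= -1e-9)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0., 1.], [2., 0.]])
        with pytest.raises(ValueError):
            cf.DistanceMatrix(bad, ["a", "b"])


# ---------------------------------------------------------------------------
# window_scan
# ---------------------------------------------------------------------------

def _is_coarsening(fine, coarse):
    """Every cluster of `fine` lies within one cluster of `coarse`."""
    mapping = {}
    for f, c in zip(fine, coarse):
        if f in mapping and mapping[f] != c:
            return False
        mapping[f] = c
    return True


class TestWindowScan:
    def test_single_window_cuts_at_max_height(self, rng):
        X = rng.normal(size=(6, 3))
        tree = cf.ward_dendrogram(cf.DistanceMatrix(
            squareform(pdist(X)), [f"c{i}" for i in range(6)]))
        scan = cf.window_scan(tree, n_windows=1)
        assert scan.n_windows == 1
        assert scan.cut_heights[0] == pytest.approx(tree.max_height)
        # strict cut below h_max leaves the final merge unmade: top split
        assert scan.cluster_counts[0] == 2

    def test_three_separated_clouds_recovered(self, rng):
        centers = np.array([[0, 0], [100, 0], [0, 100]])
        X = np.vstack([c + rng.normal(scale=0.5, size=(8, 2))
                       for c in centers])
        tree = cf.ward_dendrogram(cf.DistanceMatrix(
            squareform(pdist(X)), [f"c{i}" for i in range(24)]))
        scan = cf.window_scan(tree, 40)
        assert scan.optimal_k == 3
        truth = np.repeat([1, 2, 3], 8)
        assert cf.adjusted_rand_index(
            cf.ClusterAssignment([f"c{i}" for i in range(24)],
                                 scan.optimal_partition),
            cf.ClusterAssignment([f"c{i}" for i in range(24)], truth)) == 1.0

    def test_windows_are_nested_coarsenings(self, rng):
        X = rng.normal(size=(30, 4))
        tree = cf.ward_dendrogram(cf.DistanceMatrix(
            squareform(pdist(X)), [f"c{i}" for i in range(30)]))
        scan = cf.window_scan(tree, 25)
        for w in range(scan.n_windows - 1):
            assert _is_coarsening(scan.partitions[w], scan.partitions[w + 1])
        assert np.all(np.diff(scan.cluster_counts) <= 0)

    def test_stability_is_longest_run_fraction(self, rng):
        X = rng.normal(size=(12, 3))
        tree = cf.ward_dendrogram(cf.DistanceMatrix(
            squareform(pdist(X)), [f"c{i}" for i in range(12)]))
        scan = cf.window_scan(tree, 20)
        keys = [p.tobytes() for p in scan.partitions]
        best_key = keys[scan.optimal_index]
        longest, run = 0, 0
        for k in keys:
            run = run + 1 if k == best_key else 0
            longest = max(longest, run)
        assert scan.stability == pytest.approx(longest / 20)

    def test_invalid_window_count(self, rng):
        X = rng.normal(size=(5, 2))
        tree = cf.ward_dendrogram(cf.DistanceMatrix(
            squareform(pdist(X)), [f"c{i}" for i in range(5)]))
        with pytest.raises(ValueError):
            cf.window_scan(tree, 0)


# ---------------------------------------------------------------------------
# bagging
# ---------------------------------------------------------------------------

class TestBagOnce:
    def _distance(self, rng, n=30):
        X = rng.normal(size=(n, 4))
        return cf.DistanceMatrix(squareform(pdist(X)),
                                 [f"c{i}" for i in range(n)])

    def test_full_proportion_reproduces_original_k(self, rng):
        d = self._distance(rng)
        tree = cf.ward_dendrogram(d)
        k_orig = cf.window_scan(tree, 40).optimal_k
        # without replacement at proportion 1 the subsample is the identity
        k = cf.bag_once(d, 1.0, np.random.default_rng(0), 40)
        assert k == k_orig

    def test_sample_entries_bit_identical_to_parent(self, rng):
        d = self._distance(rng)
        k, sample = cf.bag_once(d, 0.8, np.random.default_rng(3), 40,
                                replace=True, return_sample=True)
        idx = sample.indices
        for a in range(len(idx)):
            for b in range(len(idx)):
                assert sample.sub_distance.values[a, b] == \
                    d.values[idx[a], idx[b]]

    def test_duplicate_pair_off_diagonal_zero(self):
        # force duplicates by sampling 10 cells from 5 with replacement
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        d = cf.DistanceMatrix(squareform(pdist(X)),
                              [f"c{i}" for i in range(5)])
        k, sample = cf.bag_once(d, 2.0, np.random.default_rng(1), 10,
                                replace=True, return_sample=True)
        idx = sample.indices
        dup = [(a, b) for a in range(len(idx)) for b in range(a + 1, len(idx))
               if idx[a] == idx[b]]
        assert dup, "with-replacement draw of 10 from 5 must duplicate"
        for a, b in dup:
            assert sample.sub_distance.values[a, b] == 0.0

    def test_fixed_seed_is_deterministic(self, rng):
        d = self._distance(rng)
        ks = {cf.bag_once(d, 0.8, np.random.default_rng(7), 40)
              for _ in range(3)}
        assert len(ks) == 1

    def test_degenerate_identical_subsample_returns_one(self):
        d = cf.DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        with pytest.warns(UserWarning, match="degenerate"):
            k = cf.bag_once(d, 1.0, np.random.default_rng(0), 10)
        assert k == 1


class TestScoreCluster:
    def test_recovers_three_planted_clusters(self, three_cluster_norm):
        norm, truth, markers, genes = three_cluster_norm
        result = cf.score_cluster(norm, genes, n_bags=30, seed=5)
        assert result.voted_k == 3
        assert cf.adjusted_rand_index(result.final_partition, truth) == 1.0
        assert not result.fallback_used

    def test_single_bag_vote_equals_that_bag(self, three_cluster_norm):
        norm, truth, markers, genes = three_cluster_norm
        result = cf.score_cluster(norm, genes, n_bags=1, seed=2)
        assert result.voted_k == result.per_bag_k[0]

    def test_same_seed_bit_identical(self, three_cluster_norm):
        norm, truth, markers, genes = three_cluster_norm
        r1 = cf.score_cluster(norm, genes, n_bags=5, seed=3)
        r2 = cf.score_cluster(norm, genes, n_bags=5, seed=3)
        np.testing.assert_array_equal(r1.per_bag_k, r2.per_bag_k)
        np.testing.assert_array_equal(r1.final_partition.labels,
                                      r2.final_partition.labels)
        np.testing.assert_array_equal(r1.running_mean, r2.running_mean)

    def test_running_mean_is_cumulative_average(self, three_cluster_norm):
        norm, truth, markers, genes = three_cluster_norm
        r = cf.score_cluster(norm, genes, n_bags=8, seed=4)
        expected = np.cumsum(r.per_bag_k) / np.arange(1, 9)
        np.testing.assert_allclose(r.running_mean, expected)

    def test_voted_k_is_mode_with_ties_to_smaller(self, three_cluster_norm):
        norm, truth, markers, genes = three_cluster_norm
        r = cf.score_cluster(norm, genes, n_bags=12, seed=6)
        vals, counts = np.unique(r.per_bag_k, return_counts=True)
        assert r.voted_k == vals[counts == counts.max()].min()

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_recovery_across_cluster_counts(self, k):
        params = cf.SimulationParams(n_cells_per_cluster=(40,) * k, seed=k)
        expr, truth, _ = cf.simulate_mixed_population(params)
        genes = cf.select_variable_genes(expr, 20 * k)
        norm = cf.normalize_log_cpm(expr)
        result = cf.score_cluster(norm, genes, n_bags=10, seed=k)
        assert result.voted_k == k
        assert cf.adjusted_rand_index(result.final_partition, truth) == 1.0


class TestEstimatorInterface:
    def test_fit_predict_and_params(self, three_cluster_norm):
        norm, truth, markers, genes = three_cluster_norm
        X = norm.subset_genes(genes).values
        est = cf.StabilityClustering(n_bags=5, random_state=0)
        labels = est.fit_predict(X)
        assert labels.shape == (X.shape[0],)
        assert est.get_params()["n_bags"] == 5
        clone_params = cf.StabilityClustering().set_params(
            **est.get_params()).get_params()
        assert clone_params == est.get_params()

    def test_newick_export_parses(self, rng):
        X = rng.normal(size=(6, 3))
        tree = cf.ward_dendrogram(cf.DistanceMatrix(
            squareform(pdist(X)), [f"c{i}" for i in range(6)]))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 5
        from io import StringIO
        from Bio import Phylo
        parsed = Phylo.read(StringIO(nwk), "newick")
        assert parsed.count_terminals() == 6
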