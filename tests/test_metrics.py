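"""Weighted graph and MST measures against closed forms and brute force."""

import numpy as np
import pytest

import _oracles as oracle
from plinet.metrics import (
    SpanningTree,
    build_mst,
    char_path_length,
    compute_measures,
    kappa_w,
    modularity,
    mst_metrics,
    normalize_measures,
    shuffle_surrogate,
    weighted_clustering,
)


def _sym(W):
    W = np.asarray(W, float)
    np.fill_diagonal(W, 0)
    return (W + W.T) / 2


def _star_tree(n):
    return SpanningTree([str(i) for i in range(n)],
                        [(0, j, 1.0) for j in range(1, n)])


def _path_tree(n):
    return SpanningTree([str(i) for i in range(n)],
                        [(i, i + 1, 1.0) for i in range(n - 1)])


class TestWeightedClustering:
    def test_uniform_triangle_reduces_to_weight(self):
        for w in (0.2, 0.7, 1.0):
            W = _sym(np.full((3, 3), w))
            assert weighted_clustering(W) == pytest.approx(w)

    def test_star_has_no_triangles(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.8
        assert weighted_clustering(W) == 0.0

    def test_matches_binary_clustering_on_01_graphs(self, rng):
        # every graph on 5 nodes with random edge patterns
        for _ in range(100):
            A = (oracle.random_weighted_graph(rng, 5, density=0.6) > 0).astype(float)
            assert weighted_clustering(A) == pytest.approx(
                oracle.binary_clustering(A))

    def test_matches_triple_sum_oracle_on_weighted_graphs(self, rng):
        for _ in range(50):
            W = oracle.random_weighted_graph(rng, 6, density=0.8)
            assert weighted_clustering(W) == pytest.approx(
                oracle.weighted_clustering_triple(W))


class TestCharPathLength:
    def test_three_node_chain(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        # distances {2, 2, 4} -> mean 8/3
        assert char_path_length(W) == pytest.approx(8 / 3)

    def test_uniform_complete_graph(self):
        for w in (0.25, 0.5):
            W = _sym(np.full((6, 6), w))
            assert char_path_length(W) == pytest.approx(1 / w)

    def test_matches_path_enumeration_oracle(self, rng):
        for _ in range(100):
            W = oracle.random_weighted_graph(rng, 6, density=0.7)
            if not np.isfinite(oracle.char_path_length(W)):
                continue
            assert char_path_length(W, warn_disconnected=False) == pytest.approx(
                oracle.char_path_length(W))


class TestKappaW:
    def test_strength_regular_graph_gives_common_strength(self):
        W = _sym(np.full((21, 21), 0.2))
        assert kappa_w(W) == pytest.approx(4.0)

    def test_unit_weight_star(self):
        W = np.zeros((4, 4))
        W[0, 1:] = W[1:, 0] = 1.0
        # strengths {3,1,1,1} -> 12/6
        assert kappa_w(W) == pytest.approx(2.0)

    def test_at_least_mean_strength(self, rng):
        # Cauchy-Schwarz: kappa_w >= mean strength
        for _ in range(50):
            W = oracle.random_weighted_graph(rng, 7)
            s = W.sum(axis=1)
            assert kappa_w(W) >= s.mean() - 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            kappa_w(np.zeros((4, 4)))


class TestModularity:
    def test_two_disconnected_triangles(self):
        W = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            W[a, b] = W[b, a] = 1.0
        assert modularity(W, seed=0) == pytest.approx(0.5)
        assert oracle.best_modularity(W) == pytest.approx(0.5)

    def test_complete_uniform_graph_has_no_structure(self):
        W = _sym(np.full((8, 8), 0.5))
        assert modularity(W, seed=0) == pytest.approx(0.0, abs=1e-9)

    def test_never_exceeds_exhaustive_optimum(self, rng):
        for k in range(30):
            W = oracle.random_weighted_graph(rng, 6, density=0.7)
            if W.sum() == 0:
                continue
            q = modularity(W, seed=k)
            assert q <= oracle.best_modularity(W) + 1e-9

    def test_seed_deterministic(self, rng):
        W = oracle.random_weighted_graph(rng, 10)
        assert modularity(W, seed=3) == modularity(W, seed=3)


class TestBuildMst:
    def test_unique_maximum_tree(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.9
        W[1, 2] = W[2, 1] = 0.8
        W[0, 2] = W[2, 0] = 0.1
        tree = build_mst(W)
        assert sorted((i, j) for i, j, _ in tree.edges) == [(0, 1), (1, 2)]

    def test_tree_shape_invariants(self, rng):
        W = oracle.random_weighted_graph(rng, 9)
        tree = build_mst(W)
        assert tree.M == tree.N - 1  # connectivity/acyclicity in validator

    def test_total_weight_matches_enumeration(self, rng):
        for _ in range(100):
            W = oracle.random_weighted_graph(rng, 6, density=0.9)
            try:
                tree = build_mst(W)
            except ValueError:
                assert not np.isfinite(oracle.max_spanning_tree_weight(W))
                continue
            assert tree.total_weight() == pytest.approx(
                oracle.max_spanning_tree_weight(W))

    def test_invariant_to_positive_scaling(self, rng):
        W = oracle.random_weighted_graph(rng, 8)
        e1 = [(i, j) for i, j, _ in build_mst(W).edges]
        e2 = [(i, j) for i, j, _ in build_mst(3.7 * W).edges]
        assert e1 == e2

    def test_deterministic_under_ties(self):
        W = _sym(np.full((5, 5), 0.4))
        e1 = [(i, j) for i, j, _ in build_mst(W).edges]
        e2 = [(i, j) for i, j, _ in build_mst(W).edges]
        assert e1 == e2 == [(0, 1), (0, 2), (0, 3), (0, 4)]

    def test_disconnected_graph_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        with pytest.raises(ValueError, match="disconnected"):
            build_mst(W)


class TestMstMetrics:
    def test_star_21_closed_forms(self):
        bc, diam, ecc, leaf = mst_metrics(_star_tree(21))
        assert leaf == pytest.approx(1.0)
        assert diam == pytest.approx(0.1)
        assert bc == pytest.approx(1.0)
        assert ecc == pytest.approx((1 + 20 * 2) / 21 / 20)

    def test_path_21_closed_forms(self):
        bc, diam, ecc, leaf = mst_metrics(_path_tree(21))
        assert leaf == pytest.approx(0.1)
        assert diam == pytest.approx(1.0)
        assert bc == pytest.approx(100 / 190)

    def test_matches_bfs_oracle_on_random_trees(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 9))
            edges = oracle.random_tree(rng, n)
            tree = SpanningTree([str(v) for v in range(n)],
                                [(min(i, j), max(i, j), 1.0) for i, j in edges])
            got = mst_metrics(tree)
            np.testing.assert_allclose(got, oracle.tree_metrics(edges, n))

    def test_metrics_bounded(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 10))
            edges = oracle.random_tree(rng, n)
            tree = SpanningTree([str(v) for v in range(n)],
                                [(min(i, j), max(i, j), 1.0) for i, j in edges])
            bc, diam, ecc, leaf = mst_metrics(tree)
            M = n - 1
            assert 0 <= bc <= 1 and 2 / M <= diam <= 1
            assert 0 <= ecc <= 1 and min(2 / M, 1.0) <= leaf <= 1

    def test_leaf_and_diameter_anticorrelate(self, rng):
        # star-like trees have many leaves and small diameter
        from scipy.stats import spearmanr

        leafs, diams = [], []
        for _ in range(250):
            edges = oracle.random_tree(rng, 7)
            tree = SpanningTree([str(v) for v in range(7)],
                                [(min(i, j), max(i, j), 1.0)
                                 for i, j in edges])
            _, diam, _, leaf = mst_metrics(tree)
            leafs.append(leaf)
            diams.append(diam)
        assert spearmanr(leafs, diams).statistic < 0

    def test_tiny_tree_rejected(self):
        with pytest.raises(ValueError):
            mst_metrics(SpanningTree(["a", "b"], [(0, 1, 1.0)]))


class TestNormalization:
    def test_uniform_complete_graph_normalizes_to_one(self):
        W = _sym(np.full((10, 10), 0.3))
        gamma, lam = normalize_measures(W, n_surrogates=5, seed=0)
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)

    def test_shuffled_input_near_one(self, rng):
        # observed network that is itself a weight shuffle: gamma, lambda ~ 1
        base = oracle.random_weighted_graph(rng, 15, low=0.05, high=0.6)
        gammas, lams = [], []
        for seed in range(20):
            W = shuffle_surrogate(base, np.random.default_rng(seed + 100))
            g, l = normalize_measures(W, n_surrogates=50, seed=seed)
            gammas.append(g)
            lams.append(l)
        assert abs(np.mean(gammas) - 1) < 0.03
        assert abs(np.mean(lams) - 1) < 0.03

    def test_seed_deterministic(self, rng):
        W = oracle.random_weighted_graph(rng, 8)
        assert normalize_measures(W, 10, seed=5) == \
            normalize_measures(W, 10, seed=5)


class TestPermutationInvariance:
    def test_measures_invariant_under_node_relabeling(self, rng):
        W = oracle.random_weighted_graph(rng, 9)
        perm = rng.permutation(9)
        Wp = W[np.ix_(perm, perm)]
        assert weighted_clustering(W) == pytest.approx(weighted_clustering(Wp))
        assert char_path_length(W) == pytest.approx(char_path_length(Wp))
        assert kappa_w(W) == pytest.approx(kappa_w(Wp))


class TestComputeMeasures:
    def test_returns_all_nine_in_valid_ranges(self, rng):
        W = oracle.random_weighted_graph(rng, 12, low=0.1, high=0.9)
        nm = compute_measures(W, n_surrogates=10, seed=0)
        d = nm.as_dict()
        assert len(d) == 9
        for key in ("mst_bc_max", "mst_diameter", "mst_eccentricity", "mst_leaf"):
            assert 0 <= d[key] <= 1
        assert d["gamma"] > 0 and d["lambda_"] > 0 and d["kappa_w"] >= 0
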