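"""Tests for graph construction, the 24 measures and community detection,
cross-checked against the brute-force oracle implementations."""

import numpy as np
import networkx as nx
import pytest

import eeglevels as el
from eeglevels.graphs import (COMMUNITY_ALGORITHMS, CommunityPartition,
                              GraphConfig, build_graph, detect_communities)

from _bruteforce import (exhaustive_best_modularity, reference_community_apl,
                         reference_measures)
from conftest import random_weight_matrix


def complete_graph(n):
    W = np.ones((n, n))
    np.fill_diagonal(W, 0.0)
    return build_graph(W + np.eye(n))  # diagonal stripped by build_graph


class TestBuildGraph:
    def test_uniform_offdiagonal_maps_to_triangle(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 1.0)
        g = build_graph(vals)
        assert g.n_edges == 3
        assert np.allclose(g.W[np.triu_indices(3, 1)], 0.5)

    def test_absolute_value_mode_flips_negative_correlations(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 1.0)
        vals[0, 1] = vals[1, 0] = -0.5
        g = build_graph(vals)
        assert g.W[0, 1] == 0.5

    def test_signed_mode_drops_negative_edges(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 1.0)
        vals[0, 1] = vals[1, 0] = -0.5
        g = build_graph(vals, GraphConfig(weight_mode="signed"))
        assert g.W[0, 1] == 0.0

    def test_proportional_threshold_keeps_strongest_edges(self):
        # sort-and-cut oracle: exactly 3 of 6 distinct |r| survive at d=0.5
        iu = np.triu_indices(4, 1)
        vals = np.eye(4)
        vals[iu] = [0.1, 0.9, 0.3, 0.7, 0.5, 0.2]
        vals = np.triu(vals, 1) + np.triu(vals, 1).T + np.eye(4)
        g = build_graph(vals, GraphConfig(threshold=0.5))
        kept = set(np.round(g.W[iu][g.W[iu] > 0], 3))
        assert g.n_edges == 3
        assert kept == {0.9, 0.7, 0.5}

    def test_isolated_node_recorded_not_raised(self):
        vals = np.eye(4)
        vals[0, 1] = vals[1, 0] = 0.9
        vals[2, 3] = vals[3, 2] = 0.8
        vals[0, 2] = vals[2, 0] = 0.7
        g = build_graph(vals, GraphConfig(threshold=0.17))  # keeps 1 of 6
        assert any("isolated" in note for note in g.notes)


class TestStandardMeasures:
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_complete_graph_identities(self, n):
        m = el.compute_standard_measures(complete_graph(n))
        assert m["density"] == pytest.approx(1.0)
        assert m["transitivity"] == pytest.approx(1.0)
        assert m["average_path_length"] == pytest.approx(1.0)
        assert m["diameter"] == pytest.approx(1.0)
        assert m["mean_degree"] == pytest.approx(n - 1)
        assert m["closeness_centrality"] == pytest.approx(1.0)
        assert m["betweenness_centrality"] == pytest.approx(0.0)
        assert m["k_core"] == n - 1

    def test_star_graph_degree_correlations(self):
        # 5 leaves: no triangles, and perfect degree disassortativity
        W = np.zeros((6, 6))
        W[0, 1:] = W[1:, 0] = 1.0
        m = el.compute_standard_measures(build_graph(W + np.eye(6)))
        assert m["transitivity"] == pytest.approx(0.0)
        assert m["assortativity"] == pytest.approx(-1.0)

    def test_cycle_average_path_length(self):
        C5 = nx.to_numpy_array(nx.cycle_graph(5))
        m = el.compute_standard_measures(build_graph(C5 + np.eye(5)))
        assert m["average_path_length"] == pytest.approx(1.5)
        assert m["diameter"] == pytest.approx(2.0)

    def test_matches_bruteforce_oracle_on_random_graphs(self, rng):
        # definition-level oracle: exhaustive relaxation and definition sums
        for trial in range(40):
            n = int(rng.integers(4, 13))
            W = random_weight_matrix(rng, n)
            if not W.any():
                continue
            for binary in (False, True):
                cfg = GraphConfig(threshold=1.0 if binary else None)
                mine = el.compute_standard_measures(build_graph(W, cfg))
                ref = reference_measures(W, binary_degrees=binary)
                for key, val in mine.items():
                    assert val == pytest.approx(ref[key], abs=1e-9), (trial, key)

    def test_permutation_invariance(self, rng):
        W = random_weight_matrix(rng, 9)
        perm = rng.permutation(9)
        a = el.compute_standard_measures(build_graph(W))
        b = el.compute_standard_measures(build_graph(W[np.ix_(perm, perm)]))
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9)

    def test_adding_edge_monotonicity(self, rng):
        # an extra edge can only shorten paths and raise density
        for _ in range(10):
            W = random_weight_matrix(rng, 8, p_edge=0.6)
            g = build_graph(W)
            missing = np.argwhere((W == 0) & ~np.eye(8, dtype=bool))
            if not len(missing):
                continue
            i, j = missing[0]
            W2 = W.copy()
            W2[i, j] = W2[j, i] = 0.5
            before = el.compute_standard_measures(build_graph(W))
            after = el.compute_standard_measures(build_graph(W2))
            assert after["density"] >= before["density"]
            # only comparable when the largest component did not change
            if before["efficiency"] > 0:
                assert after["efficiency"] >= before["efficiency"] - 1e-12

    def test_disconnected_graph_flagged(self):
        W = np.zeros((6, 6))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        W[3, 4] = W[4, 3] = 1.0
        g = build_graph(W + np.eye(6))
        el.compute_standard_measures(g)
        assert any("components" in note for note in g.notes)


def two_cliques(k=4):
    n = 2 * k
    A = np.zeros((n, n))
    A[:k, :k] = 1.0
    A[k:, k:] = 1.0
    np.fill_diagonal(A, 0.0)
    return build_graph(A + np.eye(n))


class TestCommunities:
    def test_two_disjoint_cliques_recovered_by_every_algorithm(self):
        g = two_cliques()
        expected = [0, 0, 0, 0, 1, 1, 1, 1]
        for alg in COMMUNITY_ALGORITHMS:
            part = detect_communities(g, alg, seed=3)
            assert part.membership.tolist() == expected, alg

    def test_clique_split_is_the_modularity_optimum(self):
        # exhaustive enumeration over all partitions of the 8 nodes
        g = two_cliques()
        _, best = exhaustive_best_modularity(g.W)
        assert sorted(map(sorted, best)) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_complete_graph_single_community_for_modularity_methods(self):
        g = complete_graph(6)
        for alg in ("fastgreedy", "leading_eigenvector", "edge_betweenness",
                    "multilevel"):
            assert detect_communities(g, alg, seed=0).n_communities == 1, alg

    def test_stochastic_detectors_reproducible_at_fixed_seed(self, rng):
        W = random_weight_matrix(rng, 15, p_edge=0.4)
        g = build_graph(W)
        for alg in ("infomap", "label_propagation", "spinglass", "multilevel"):
            a = detect_communities(g, alg, seed=42).membership
            b = detect_communities(g, alg, seed=42).membership
            assert np.array_equal(a, b), alg

    def test_spinglass_disconnected_fallback_noted(self):
        part = detect_communities(two_cliques(), "spinglass", seed=0)
        assert part.n_communities == 2
        assert any("per-component" in note for note in part.notes)

    def test_membership_canonical_order(self):
        # community ids sorted by size desc then smallest member
        part = CommunityPartition("x", np.array([2, 2, 0, 0, 0, 1]))
        assert part.membership.tolist() == [1, 1, 0, 0, 0, 2]


class TestCommunityAPL:
    def test_complete_clique_single_community(self):
        g = build_graph(np.ones((4, 4)))
        assert el.largest_community_apl(g, CommunityPartition("x", np.zeros(4))) == 1.0

    def test_cycle_as_one_community(self):
        C5 = nx.to_numpy_array(nx.cycle_graph(5))
        g = build_graph(C5 + np.eye(5))
        assert el.largest_community_apl(g, CommunityPartition("x", np.zeros(5))) == 1.5

    def test_bridged_cliques_partitioned_into_cliques(self):
        # two K3s joined by one edge; largest (tied) community is a clique
        A = np.zeros((6, 6))
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        np.fill_diagonal(A, 0.0)
        A[2, 3] = A[3, 2] = 1.0
        g = build_graph(A + np.eye(6))
        part = detect_communities(g, "fastgreedy", seed=0)
        assert sorted(np.bincount(part.membership).tolist()) == [3, 3]
        assert el.largest_community_apl(g, part) == pytest.approx(1.0)

    def test_singleton_community_returns_zero_with_note(self):
        g = build_graph(np.ones((3, 3)))
        part = CommunityPartition("x", np.array([0, 1, 2]))  # all singletons
        assert el.largest_community_apl(g, part) == 0.0
        assert any("single node" in n for n in part.notes)

    def test_matches_bruteforce_on_random_partitions(self, rng):
        for _ in range(20):
            W = random_weight_matrix(rng, 10, p_edge=0.6)
            if not W.any():
                continue
            g = build_graph(W)
            part = detect_communities(g, "multilevel", seed=int(rng.integers(100)))
            assert el.largest_community_apl(g, part) == pytest.approx(
                reference_community_apl(W, part.members(0)), abs=1e-9)


class TestLevelC:
    def test_feature_vector_has_24_named_entries(self, tiny_segments):
        m = el.pearson_matrix(tiny_segments[0])
        feats = el.compute_feature_vector(m, GraphConfig(threshold=0.3), seed=0)
        assert set(feats) == set(el.ALL_MEASURES)
        assert len(feats) == 24
        assert all(np.isfinite(v) for v in feats.values())

    def test_assemble_shape_and_labels(self, tiny_segments):
        mats = el.connectivity_matrices(tiny_segments)
        tab = el.assemble_level_c(mats, GraphConfig(threshold=0.3), seed=0)
        assert tab.X.shape == (len(mats), 24)
        assert (tab.y == 0).sum() == 4

    def test_window_summary_constant_cohort_identical_medians(self):
        vals = np.eye(5)
        iu = np.triu_indices(5, 1)
        vals[iu] = np.linspace(0.2, 0.8, 10)
        vals = np.triu(vals, 1) + np.triu(vals, 1).T + np.eye(5)
        mats = [el.connectivity.ConnectivityMatrix(f"s{i}", w, int(w != 1),
                                                   list("ABCDE"), vals)
                for i in range(3) for w in (1, 2, 3)]
        tab = el.assemble_level_c(mats, GraphConfig(), seed=0)
        summary = el.window_measure_summary(tab)
        for measure in ("closeness_centrality", "assortativity"):
            medians = summary[summary.measure == measure]["median"].tolist()
            assert len(set(np.round(medians, 12))) == 1
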