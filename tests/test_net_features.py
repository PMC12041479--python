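import networkx as nx
import numpy as np
import pytest

import _oracles as oracle
from conftest import random_adjacency
from mea_netpharm import (
    COMMUNITY_METHODS,
    community_apl,
    detect_communities,
    graph_features,
    scalar_measures,
)


def adjacency(n, edges):
    A = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return A


K5 = adjacency(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
P4 = adjacency(4, [(0, 1), (1, 2), (2, 3)])
STAR5 = adjacency(5, [(0, i) for i in range(1, 5)])
TWO_K4_BRIDGE = adjacency(
    8,
    [(i, j) for i in range(4) for j in range(i + 1, 4)]
    + [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
    + [(3, 4)],
)


class TestClosedForms:
    def test_complete_graph_k5(self):
        m = scalar_measures(K5)
        assert m["density"] == 1.0
        assert m["mean_degree"] == 4.0
        assert m["smd"] == 16.0
        assert m["complexity"] == 4.0
        assert m["ed"] == pytest.approx(0.0)
        assert m["transitivity"] == 1.0
        assert m["apl"] == 1.0
        assert m["diameter"] == 1.0
        assert m["efficiency"] == 1.0
        assert m["k_core"] == 4.0
        assert m["bc"] == 0.0
        assert m["assortativity"] == 0.0  # undefined on regular graphs -> 0

    def test_path_graph_p4(self):
        m = scalar_measures(P4)
        assert m["density"] == 0.5
        assert m["mean_degree"] == 1.5
        assert m["diameter"] == 3.0
        assert m["apl"] == pytest.approx(10 / 6)
        assert m["efficiency"] == pytest.approx(13 / 18)
        assert m["bc"] == pytest.approx(1 / 3)
        assert m["transitivity"] == 0.0

    def test_star_graph(self):
        m = scalar_measures(STAR5)
        assert m["smd"] == 4.0
        assert m["complexity"] == 2.5
        assert m["ed"] == pytest.approx(-(0.8 * np.log2(0.8) + 0.2 * np.log2(0.2)))
        assert m["transitivity"] == 0.0

    def test_edgeless_graph_conventions(self):
        m = scalar_measures(np.zeros((4, 4), dtype=np.uint8))
        assert m["apl"] == m["diameter"] == m["eccentricity"] == 0.0
        assert m["density"] == m["efficiency"] == m["mean_degree"] == 0.0

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError):
            scalar_measures(np.zeros((1, 1), dtype=np.uint8))


class TestRandomGraphOracles:
    def test_distance_measures_match_bfs_oracle(self, er_graphs):
        for A in er_graphs:
            m = scalar_measures(A)
            assert m["apl"] == pytest.approx(oracle.apl_largest_component(A))
            assert m["diameter"] == pytest.approx(oracle.diameter_largest_component(A))
            assert m["eccentricity"] == pytest.approx(
                oracle.mean_eccentricity_largest_component(A)
            )
            assert m["efficiency"] == pytest.approx(oracle.global_efficiency(A))
            assert m["cc"] == pytest.approx(oracle.mean_closeness(A))

    def test_triangle_and_degree_measures_match_oracles(self, er_graphs):
        for A in er_graphs:
            m = scalar_measures(A)
            n = A.shape[0]
            deg = A.sum(axis=1).astype(float)
            assert m["transitivity"] == pytest.approx(oracle.transitivity(A))
            assert m["mean_degree"] == pytest.approx(deg.mean())
            assert m["smd"] == pytest.approx((deg**2).mean())
            assert m["density"] == pytest.approx(A.sum() / (n * (n - 1)))

    def test_centralities_match_networkx(self, er_graphs):
        for A in er_graphs:
            if A.sum() == 0:
                continue
            m = scalar_measures(A)
            g = nx.from_numpy_array(A)
            bc = np.mean(list(nx.betweenness_centrality(g, normalized=True).values()))
            assert m["bc"] == pytest.approx(bc, abs=1e-9)
            assert m["k_core"] == max(nx.core_number(g).values())
            assort = nx.degree_assortativity_coefficient(g)
            expected = 0.0 if not np.isfinite(assort) else assort
            assert m["assortativity"] == pytest.approx(expected, abs=1e-8)
            knn_map = nx.average_neighbor_degree(g)
            vals = [v for node, v in knn_map.items() if g.degree[node] > 0]
            assert m["knn"] == pytest.approx(np.mean(vals))

    def test_eigenvector_centrality_matches_power_iteration(self, rng):
        for _ in range(10):
            A = random_adjacency(rng, 10, 0.5)
            g = nx.from_numpy_array(A)
            if A.sum() == 0 or not nx.is_connected(g):
                continue
            m = scalar_measures(A)
            ev = oracle.max_normalized_eigenvector(A.astype(float))
            # igraph's ARPACK solve is iterative; compare at its tolerance
            assert m["ec"] == pytest.approx(ev.mean(), abs=1e-4)


class TestInvariants:
    def test_degree_moment_inequality_and_consistency(self, er_graphs):
        for A in er_graphs:
            m = scalar_measures(A)
            assert m["smd"] - m["mean_degree"] ** 2 >= -1e-12
            if m["mean_degree"] > 0:
                assert m["complexity"] == pytest.approx(m["smd"] / m["mean_degree"])
            deg = A.sum(axis=1)
            if len(set(deg.tolist())) == 1:  # regular graph: equality case
                assert m["smd"] == pytest.approx(m["mean_degree"] ** 2)

    def test_scalar_measures_invariant_under_relabeling(self, rng):
        for _ in range(5):
            A = random_adjacency(rng, 9, 0.4)
            perm = rng.permutation(9)
            fa = scalar_measures(A)
            fb = scalar_measures(A[np.ix_(perm, perm)])
            for key in fa:
                assert fa[key] == pytest.approx(fb[key], abs=1e-9), key

    def test_community_features_invariant_under_relabeling_of_clear_structure(self, rng):
        # heuristic community detection only guarantees label-invariant
        # results when the partition is unambiguous
        perm = rng.permutation(8)
        fa = graph_features(TWO_K4_BRIDGE, seed=0)
        fb = graph_features(TWO_K4_BRIDGE[np.ix_(perm, perm)], seed=0)
        for key in fa:
            assert fa[key] == pytest.approx(fb[key], abs=1e-9), key


class TestCommunities:
    @pytest.mark.parametrize("method", sorted(COMMUNITY_METHODS.values()))
    def test_two_cliques_with_bridge_are_split(self, method):
        membership = detect_communities(TWO_K4_BRIDGE, method, seed=0)
        groups = {tuple(sorted(np.flatnonzero(membership == c))) for c in set(membership)}
        assert groups == {(0, 1, 2, 3), (4, 5, 6, 7)}
        assert community_apl(TWO_K4_BRIDGE, method, seed=0) == 1.0

    @pytest.mark.parametrize("method", sorted(COMMUNITY_METHODS.values()))
    def test_partition_covers_every_node(self, method, rng):
        A = random_adjacency(rng, 10, 0.3)
        membership = detect_communities(A, method, seed=1)
        assert membership.shape == (10,)
        assert np.all(membership >= 0)

    def test_edgeless_graph_gives_singletons(self):
        A = np.zeros((5, 5), dtype=np.uint8)
        assert len(set(detect_communities(A, "multilevel").tolist())) == 5
        assert community_apl(A, "multilevel") == 0.0

    @pytest.mark.parametrize(
        "method", ["fastgreedy", "multilevel", "leading_eigenvector",
                   "edge_betweenness", "label_propagation", "infomap",
                   "spinglass", "spanning_tree"],
    )
    def test_complete_graph_is_one_community(self, method):
        K6 = adjacency(6, [(i, j) for i in range(6) for j in range(i + 1, 6)])
        assert len(set(detect_communities(K6, method, seed=0).tolist())) == 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(K5, "louvainish")

    def test_community_apl_matches_bfs_oracle(self):
        # two K3 cliques plus a 5-node pendant path on one clique
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3),
                 (5, 6), (6, 7), (7, 8), (8, 9), (9, 10)]
        A = adjacency(11, edges)
        membership = detect_communities(A, "multilevel", seed=0)
        sizes = {c: int((membership == c).sum()) for c in set(membership)}
        winner = max(sizes, key=lambda c: (sizes[c], -int(np.flatnonzero(membership == c)[0])))
        nodes = np.flatnonzero(membership == winner)
        sub = A[np.ix_(nodes, nodes)]
        assert community_apl(A, "multilevel", seed=0) == pytest.approx(
            oracle.apl_largest_component(sub)
        )

    def test_stochastic_methods_deterministic_given_seed(self, rng):
        A = random_adjacency(rng, 12, 0.3)
        for method in ("infomap", "label_propagation", "spinglass"):
            a = detect_communities(A, method, seed=7)
            b = detect_communities(A, method, seed=7)
            np.testing.assert_array_equal(a, b)
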