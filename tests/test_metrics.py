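"""Graph metrics vs closed forms and exhaustive brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    brute_betweenness,
    brute_char_path_length,
    brute_floyd_warshall,
    brute_onnela_clustering,
    brute_strength,
    random_weight_matrix,
)
from fcnetopo.graph import WeightedGraph
from fcnetopo.metrics import (
    betweenness_centrality,
    characteristic_path_length,
    detect_hubs,
    global_metrics,
    node_strength,
    nodal_metrics,
    shortest_path_lengths,
    strength_variance,
    weighted_clustering,
)


class TestStrength:
    def test_triangle_and_star(self, star_graph):
        W = np.ones((3, 3)) - np.eye(3)
        assert np.array_equal(node_strength(WeightedGraph(W)), [2, 2, 2])
        assert np.array_equal(node_strength(star_graph), [4, 1, 1, 1, 1])

    def test_hand_sum(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[0, 2] = W[2, 0] = 0.4
        assert np.allclose(node_strength(WeightedGraph(W)), [0.7, 0.3, 0.4])

    def test_variance_hand_and_scaling(self):
        assert strength_variance(np.array([1.0, 1.0, 1.0])) == 0.0
        assert strength_variance(np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0)
        s = np.array([0.5, 1.5, 4.0])
        assert strength_variance(3 * s) == pytest.approx(9 * strength_variance(s))


class TestClustering:
    def test_complete_graph_all_one(self, complete_unit_graph):
        c, avg = weighted_clustering(complete_unit_graph)
        assert np.allclose(c, 1.0)
        assert avg == pytest.approx(1.0)

    def test_star_has_no_triangles(self, star_graph):
        c, avg = weighted_clustering(star_graph)
        assert np.all(c == 0.0)
        assert avg == 0.0

    def test_weighted_triangle_geometric_mean(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.5
        W[1, 2] = W[2, 1] = 1.0
        c, _ = weighted_clustering(WeightedGraph(W))
        assert np.allclose(c, 0.25 ** (1.0 / 3.0), atol=1e-12)
        assert c[0] == pytest.approx(0.6300, abs=1e-4)

    def test_barrat_variant_unweighted_agrees_with_triangle_fraction(self):
        W = np.ones((4, 4)) - np.eye(4)
        c, avg = weighted_clustering(WeightedGraph(W), variant="barrat")
        assert np.allclose(c, 1.0)


class TestPathLength:
    def test_unit_chain(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        d = shortest_path_lengths(WeightedGraph(W))
        assert d[0, 2] == pytest.approx(2.0)

    def test_reciprocal_weight_lengths(self, chain_graph):
        d = shortest_path_lengths(chain_graph)
        assert d[0, 1] == pytest.approx(2.0)
        assert d[1, 2] == pytest.approx(4.0)
        assert d[0, 2] == pytest.approx(6.0)
        L, n_disc = characteristic_path_length(d)
        assert L == pytest.approx(4.0)
        assert n_disc == 0

    def test_disconnected_pairs_counted_not_propagated(self, chain_graph):
        W = np.zeros((4, 4))
        W[:3, :3] = chain_graph.weights
        g = WeightedGraph(W)  # isolated 4th node
        L, n_disc = characteristic_path_length(shortest_path_lengths(g))
        assert L == pytest.approx(4.0)
        assert n_disc == 3

    def test_fully_disconnected_is_error(self):
        with pytest.raises(ValueError, match="disconnected"):
            characteristic_path_length(shortest_path_lengths(WeightedGraph(np.zeros((3, 3)))))


class TestBetweenness:
    def test_star_center(self, star_graph):
        bc, avg = betweenness_centrality(star_graph)
        assert bc[0] == pytest.approx(6.0)  # C(4,2) transiting pairs
        assert np.all(bc[1:] == 0.0)

    def test_complete_graph_zero(self, complete_unit_graph):
        bc, _ = betweenness_centrality(complete_unit_graph)
        assert np.all(bc == 0.0)

    def test_chain_middle(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        bc, _ = betweenness_centrality(WeightedGraph(W))
        assert bc[1] == pytest.approx(1.0)


class TestHubs:
    def test_star_center_is_only_hub(self, star_graph):
        assert detect_hubs(nodal_metrics(star_graph)) == {0}

    def test_complete_graph_has_no_hubs(self, complete_unit_graph):
        assert detect_hubs(nodal_metrics(complete_unit_graph)) == set()

    def test_conjunction_required(self):
        # node 3 has highest strength but lies on no shortest path
        W = np.zeros((5, 5))
        for i, j, w in ((0, 1, 1.0), (1, 2, 1.0), (0, 3, 5.0), (1, 3, 5.0),
                        (2, 3, 5.0), (4, 3, 5.0)):
            W[i, j] = W[j, i] = w
        nm = nodal_metrics(WeightedGraph(W))
        assert np.argmax(nm.strength) == 3
        hubs = detect_hubs(nm)
        s_thr = nm.strength.mean() + nm.strength.std(ddof=1)
        b_thr = nm.betweenness.mean() + nm.betweenness.std(ddof=1)
        for h in hubs:
            assert nm.strength[h] > s_thr and nm.betweenness[h] > b_thr


class TestGlobalMetrics:
    def test_complete_graph_closed_forms(self, complete_unit_graph):
        gm = global_metrics(complete_unit_graph)
        assert gm.avg_strength == pytest.approx(3.0)
        assert gm.strength_variance == 0.0
        assert gm.avg_clustering == pytest.approx(1.0)
        assert gm.char_path_length == pytest.approx(1.0)
        assert gm.avg_betweenness == 0.0
        assert gm.density == 1.0

    def test_handshake_identity(self, rng):
        W = random_weight_matrix(7, rng)
        g = WeightedGraph(W)
        gm = global_metrics(g)
        assert gm.avg_strength == pytest.approx(2 * np.triu(W).sum() / 7, abs=1e-12)


class TestOracleEquivalence:
    """Exhaustive brute-force cross-checks on random small graphs."""

    @pytest.mark.parametrize("seed", range(25))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 9))
        W = random_weight_matrix(n, rng)
        if np.count_nonzero(np.triu(W)) < 1:
            W[0, 1] = W[1, 0] = 0.5
        g = WeightedGraph(W)
        assert np.allclose(node_strength(g), brute_strength(W), atol=1e-9)
        c, _ = weighted_clustering(g)
        assert np.allclose(c, brute_onnela_clustering(W), atol=1e-9)
        D = shortest_path_lengths(g)
        Dref = brute_floyd_warshall(W)
        assert np.allclose(D, Dref, atol=1e-9)
        if np.isfinite(Dref[np.triu_indices(n, 1)]).any():
            L, nd = characteristic_path_length(D)
            Lref, ndref = brute_char_path_length(Dref)
            assert L == pytest.approx(Lref, abs=1e-9)
            assert nd == ndref
        bc, _ = betweenness_centrality(g)
        assert np.allclose(bc, brute_betweenness(W), atol=1e-9)


class TestScaleAndPermutationProperties:
    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 30))
    @settings(max_examples=30)
    def test_weight_scaling_laws(self, c, seed):
        rng = np.random.default_rng(seed)
        W = random_weight_matrix(6, rng)
        if np.count_nonzero(np.triu(W)) < 2:
            W[0, 1] = W[1, 0] = 0.5
            W[2, 3] = W[3, 2] = 0.7
        g, gc = WeightedGraph(W), WeightedGraph(c * W)
        assert np.allclose(node_strength(gc), c * node_strength(g), atol=1e-9)
        assert np.allclose(weighted_clustering(gc)[0], weighted_clustering(g)[0], atol=1e-9)
        d, dc = shortest_path_lengths(g), shortest_path_lengths(gc)
        finite = np.isfinite(d)
        assert np.allclose(dc[finite], d[finite] / c, atol=1e-9)
        assert np.allclose(betweenness_centrality(gc)[0], betweenness_centrality(g)[0],
                           atol=1e-9)

    @given(seed=st.integers(0, 30))
    @settings(max_examples=30)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        W = random_weight_matrix(6, rng)
        perm = rng.permutation(6)
        Wp = W[np.ix_(perm, perm)]
        nm, nmp = nodal_metrics(WeightedGraph(W)), nodal_metrics(WeightedGraph(Wp))
        assert np.allclose(nmp.strength, nm.strength[perm], atol=1e-9)
        assert np.allclose(nmp.betweenness, nm.betweenness[perm], atol=1e-9)
        assert np.allclose(nmp.clustering, nm.clustering[perm], atol=1e-9)
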