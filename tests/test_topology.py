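"""Topology indices against closed forms and brute-force path oracles."""

import numpy as np
import pytest

from oracle_utils import (
    brute_force_paths,
    random_network,
    transcribe_degree_centrality,
    transcribe_efficiency,
)
from parenclitic.network import ParencliticNetwork
from parenclitic.topology import (
    TopologyFeatures,
    betweenness,
    degree_centrality_graph,
    diameter,
    efficiency,
    extract_features,
    shortest_path_matrix,
    weighted_degrees,
)


def net_from(W, mask=None):
    W = np.asarray(W, dtype=float)
    return ParencliticNetwork("t", [f"g{i}" for i in range(len(W))], W, "regression", mask)


def star(n, w=1.0):
    W = np.zeros((n, n))
    W[0, 1:] = W[1:, 0] = w
    mask = W > 0
    return net_from(W, mask)


def complete(n, w=1.0):
    W = np.full((n, n), w)
    np.fill_diagonal(W, 0.0)
    return net_from(W)


class TestDegrees:
    def test_triangle_incident_sums(self):
        W = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        assert sorted(weighted_degrees(net_from(W))) == [3, 4, 5]

    def test_all_zero_graph(self):
        assert weighted_degrees(net_from(np.zeros((4, 4)))).tolist() == [0, 0, 0, 0]

    def test_unit_star(self):
        deg = weighted_degrees(star(6))
        assert deg[0] == 5 and (deg[1:] == 1).all()


class TestShortestPaths:
    def test_triangle_detour_beats_heavy_edge(self):
        W = np.array([[0, 5, 1], [5, 0, 1], [1, 1, 0]], dtype=float)
        D = shortest_path_matrix(net_from(W))
        assert D[0, 1] == pytest.approx(2.0)  # via the third node

    def test_unit_complete_graph_all_ones(self):
        D = shortest_path_matrix(complete(5))
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(D[off], 1.0)

    def test_unreachable_pairs_are_infinite(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.5
        mask = W > 0
        D = shortest_path_matrix(net_from(W, mask))
        assert np.isinf(D[0, 2]) and D[0, 1] == 0.5

    @pytest.mark.parametrize("rep", range(25))
    def test_matches_exhaustive_enumeration(self, rep):
        rng = np.random.default_rng(1000 + rep)
        net = random_network(rng)
        D = shortest_path_matrix(net)
        D_ref, _ = brute_force_paths(net)
        np.testing.assert_allclose(D, D_ref, rtol=1e-9, atol=1e-12)


class TestDiameter:
    def test_two_edge_path(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 2.0
        W[1, 2] = W[2, 1] = 3.0
        assert diameter(net_from(W, W > 0)) == pytest.approx(5.0)

    def test_unit_complete(self):
        assert diameter(complete(6)) == pytest.approx(1.0)

    def test_disconnected_errors(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.7
        with pytest.raises(ValueError, match="disconnected"):
            diameter(net_from(W, W > 0))


class TestDegreeCentrality:
    def test_regular_graph_is_zero(self):
        assert degree_centrality_graph(complete(5)) == pytest.approx(0.0, abs=1e-15)

    def test_unit_star_is_one_over_n(self):
        for n in (4, 5, 9):
            assert degree_centrality_graph(star(n)) == pytest.approx(1.0 / n, rel=1e-12)

    def test_matches_direct_formula_transcription(self, rng):
        net = random_network(rng, n_nodes=6)
        assert degree_centrality_graph(net) == pytest.approx(
            transcribe_degree_centrality(net), rel=1e-12
        )

    def test_fewer_than_three_nodes_errors(self):
        W = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValueError, match=">= 3"):
            degree_centrality_graph(net_from(W))


class TestEfficiency:
    def test_unit_complete_is_exactly_one(self):
        assert efficiency(complete(7)) == 1.0

    def test_isolated_nodes_contribute_zero(self):
        W = np.zeros((2, 2))
        assert efficiency(net_from(W, np.zeros((2, 2), bool))) == 0.0

    def test_matches_oracle_distances(self, rng):
        net = random_network(rng, n_nodes=7)
        D_ref, _ = brute_force_paths(net)
        assert efficiency(net) == pytest.approx(transcribe_efficiency(D_ref), rel=1e-9)


class TestBetweenness:
    def test_star_center_closed_form(self):
        for n in (4, 6, 8):
            bc = betweenness(star(n))
            assert bc[0] == pytest.approx((n - 1) * (n - 2) / 2, rel=1e-12)
            assert np.allclose(bc[1:], 0.0)

    def test_unit_complete_all_zero(self):
        # direct edges (length 1) strictly beat any two-hop path (length 2)
        assert np.allclose(betweenness(complete(6)), 0.0)

    def test_tied_paths_split_counts(self):
        # square: two equal shortest paths between opposite corners
        W = np.zeros((4, 4))
        for a, b in ((0, 1), (1, 2), (2, 3), (3, 0)):
            W[a, b] = W[b, a] = 1.0
        bc = betweenness(net_from(W, W > 0))
        np.testing.assert_allclose(bc, 0.5)

    @pytest.mark.parametrize("rep", range(25))
    def test_matches_exhaustive_path_enumeration(self, rep):
        rng = np.random.default_rng(2000 + rep)
        net = random_network(rng, n_nodes=6)
        _, bc_ref = brute_force_paths(net)
        np.testing.assert_allclose(betweenness(net), bc_ref, rtol=1e-9, atol=1e-9)


class TestExtractFeatures:
    def test_homogeneous_complete_graph(self):
        c = 0.4
        f = extract_features(complete(5, c))
        assert f.mean_edge_weight == pytest.approx(c)
        assert f.var_edge_weight == 0.0
        assert f.max_edge_weight == pytest.approx(c)
        assert f.var_degree == pytest.approx(0.0, abs=1e-25)
        assert f.degree_centrality == pytest.approx(0.0, abs=1e-15)

    def test_vector_has_twelve_components_in_declared_order(self, rng):
        f = extract_features(random_network(rng, n_nodes=5))
        assert len(TopologyFeatures.ORDER) == 12
        arr = f.as_array()
        assert arr.shape == (12,)
        assert arr[0] == f.mean_edge_weight and arr[11] == f.betweenness_centrality

    def test_all_twelve_against_per_metric_oracles(self):
        rng = np.random.default_rng(77)
        net = random_network(rng, n_nodes=4, edge_prob=1.0)
        f = extract_features(net)
        w = net.weights[np.triu_indices(4, 1)]
        deg = net.weights.sum(axis=1)
        D_ref, bc_ref = brute_force_paths(net)
        paths = D_ref[np.triu_indices(4, 1)]
        assert f.mean_edge_weight == pytest.approx(w.mean(), rel=1e-12)
        assert f.var_edge_weight == pytest.approx(w.var(ddof=1), rel=1e-12)
        assert f.max_edge_weight == pytest.approx(w.max(), rel=1e-12)
        assert f.mean_degree == pytest.approx(deg.mean(), rel=1e-12)
        assert f.var_degree == pytest.approx(deg.var(ddof=1), rel=1e-12)
        assert f.max_degree == pytest.approx(deg.max(), rel=1e-12)
        assert f.mean_shortest_path == pytest.approx(paths.mean(), rel=1e-9)
        assert f.var_shortest_path == pytest.approx(paths.var(ddof=1), rel=1e-9)
        assert f.diameter == pytest.approx(paths.max(), rel=1e-9)
        assert f.degree_centrality == pytest.approx(transcribe_degree_centrality(net), rel=1e-12)
        assert f.efficiency == pytest.approx(transcribe_efficiency(D_ref), rel=1e-9)
        assert f.betweenness_centrality == pytest.approx(bc_ref.mean(), rel=1e-9)

    def test_permutation_invariance_of_graph_level_indices(self, rng):
        net = random_network(rng, n_nodes=7)
        perm = rng.permutation(7)
        pnet = ParencliticNetwork(
            "p",
            [net.gene_ids[i] for i in perm],
            net.weights[np.ix_(perm, perm)],
            net.kernel,
            net.edge_mask[np.ix_(perm, perm)],
        )
        f1, f2 = extract_features(net).as_array(), extract_features(pnet).as_array()
        np.testing.assert_allclose(f1, f2, rtol=1e-9)

    def test_inverse_length_mode_uses_reciprocal_weights(self):
        W = np.array([[0, 2.0, 4.0], [2.0, 0, 4.0], [4.0, 4.0, 0]])
        net = net_from(W)
        D = shortest_path_matrix(net, length_mode="inverse")
        # direct edge 1/4 beats the two-hop 1/2 + 1/2
        assert D[0, 2] == pytest.approx(0.25)
        f = extract_features(net, length_mode="inverse")
        assert f.mean_edge_weight == pytest.approx(W[np.triu_indices(3, 1)].mean())

    def test_scaling_laws_under_uniform_weight_scaling(self, rng):
        net = random_network(rng, n_nodes=6)
        c = 3.7
        scaled = ParencliticNetwork(
            "c", net.gene_ids, c * net.weights, net.kernel, net.edge_mask
        )
        f, fc = extract_features(net), extract_features(scaled)
        assert fc.mean_edge_weight == pytest.approx(c * f.mean_edge_weight, rel=1e-9)
        assert fc.var_edge_weight == pytest.approx(c**2 * f.var_edge_weight, rel=1e-9)
        assert fc.max_edge_weight == pytest.approx(c * f.max_edge_weight, rel=1e-9)
        assert fc.mean_shortest_path == pytest.approx(c * f.mean_shortest_path, rel=1e-9)
        assert fc.diameter == pytest.approx(c * f.diameter, rel=1e-9)
        assert fc.efficiency == pytest.approx(f.efficiency / c, rel=1e-9)
        # with the printed normalization, graph degree centrality is linear in c
        assert fc.degree_centrality == pytest.approx(c * f.degree_centrality, rel=1e-9)
        assert fc.betweenness_centrality == pytest.approx(f.betweenness_centrality, rel=1e-9)

    def test_disconnected_errors_unless_largest_component(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        W[0, 2] = W[2, 0] = 1.0
        mask = W > 0
        net = net_from(W, mask)  # node 3 isolated
        with pytest.raises(ValueError, match="disconnected"):
            extract_features(net)
        f = extract_features(net, largest_component=True)
        assert f.diameter == pytest.approx(1.0)
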