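"""Centrality, bridge centrality, z-scores and layout."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_network
from oracles import shortest_path_oracle

from nssinet import (
    bridge_metrics,
    centrality_table,
    fruchterman_reingold,
    shortest_path_metrics,
    strength_and_ei,
    z_standardize,
)
from nssinet.ggm import network_from_weights


def _net(W, communities=None):
    return network_from_weights(np.asarray(W, dtype=float), communities=communities)


class TestStrengthAndEI:
    def test_signed_and_absolute_sums(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[0, 2] = W[2, 0] = -0.2
        tab = strength_and_ei(_net(W))
        assert tab.loc["V1", "strength"] == pytest.approx(0.5)
        assert tab.loc["V1", "expected_influence"] == pytest.approx(0.1)

    def test_empty_network_is_all_zero(self):
        tab = strength_and_ei(_net(np.zeros((4, 4))))
        assert (tab == 0).all().all()

    def test_matches_row_loop_oracle(self, rng):
        net = random_network(rng, 6)
        tab = strength_and_ei(net)
        for i, label in enumerate(net.node_labels):
            sc = sum(abs(net.weights[i, j]) for j in range(6))
            ei = sum(net.weights[i, j] for j in range(6))
            assert tab.loc[label, "strength"] == pytest.approx(sc)
            assert tab.loc[label, "expected_influence"] == pytest.approx(ei)

    def test_handshake_identity(self, rng):
        net = random_network(rng, 7)
        total = strength_and_ei(net)["strength"].sum()
        iu = np.triu_indices(7, 1)
        assert total == pytest.approx(2 * np.abs(net.weights[iu]).sum())


class TestShortestPathMetrics:
    def test_path_graph_betweenness(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        tab = shortest_path_metrics(_net(W))
        assert tab["betweenness"].tolist() == [0.0, 1.0, 0.0]

    def test_disconnected_network_all_zero(self):
        tab = shortest_path_metrics(_net(np.zeros((4, 4))))
        assert (tab == 0).all().all()

    def test_against_enumeration_oracle(self, rng):
        for _ in range(10):
            net = random_network(rng, 5, density=0.6)
            oracle = shortest_path_oracle(net.weights)
            tab = shortest_path_metrics(net)
            np.testing.assert_allclose(
                tab["betweenness"].to_numpy(), oracle["betweenness"], atol=1e-9
            )
            np.testing.assert_allclose(
                tab["closeness"].to_numpy(), oracle["closeness"], atol=1e-9
            )

    def test_weight_scaling_preserves_betweenness(self, rng):
        net = random_network(rng, 6, density=0.5)
        scaled = _net(net.weights * 3.7)
        t1, t2 = shortest_path_metrics(net), shortest_path_metrics(scaled)
        np.testing.assert_allclose(
            t1["betweenness"].to_numpy(), t2["betweenness"].to_numpy(), atol=1e-9
        )
        # strength scales linearly instead
        np.testing.assert_allclose(
            strength_and_ei(scaled)["strength"].to_numpy(),
            3.7 * strength_and_ei(net)["strength"].to_numpy(),
        )


class TestBridgeMetrics:
    def test_one_step_cross_community_sums(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.2  # within community
        W[0, 2] = W[2, 0] = 0.3  # cross
        W[0, 3] = W[3, 0] = -0.1  # cross
        comm = {"V1": "a", "V2": "a", "V3": "b", "V4": "b"}
        tab = bridge_metrics(_net(W, comm))
        assert tab.loc["V1", "bridge_strength"] == pytest.approx(0.4)
        assert tab.loc["V1", "bridge_expected_influence"] == pytest.approx(0.2)

    def test_single_community_is_all_zero(self, rng):
        net = random_network(rng, 5, density=0.7)
        comm = {v: "only" for v in net.node_labels}
        tab = bridge_metrics(net, comm)
        raw = tab[[c for c in tab.columns if not c.startswith("z_")]]
        assert (raw == 0).all().all()

    def test_bridge_strength_bounded_by_strength(self, rng):
        comm = {f"V{i + 1}": ("a" if i < 3 else "b") for i in range(6)}
        net = random_network(rng, 6, communities=comm)
        bs = bridge_metrics(net)["bridge_strength"]
        sc = strength_and_ei(net)["strength"]
        assert (bs <= sc + 1e-12).all()

    def test_bridge_betweenness_against_enumeration(self, rng):
        for _ in range(10):
            comm_map = {f"V{i + 1}": ("a" if i % 2 else "b") for i in range(6)}
            net = random_network(rng, 6, density=0.6, communities=comm_map)
            labels = [comm_map[v] for v in net.node_labels]
            oracle = shortest_path_oracle(net.weights, communities=labels)
            tab = bridge_metrics(net)
            np.testing.assert_allclose(
                tab["bridge_betweenness"].to_numpy(),
                oracle["bridge_betweenness"],
                atol=1e-9,
            )
            np.testing.assert_allclose(
                tab["bridge_closeness"].to_numpy(),
                oracle["bridge_closeness"],
                atol=1e-9,
            )

    def test_unassigned_node_is_error(self, rng):
        net = random_network(rng, 4)
        with pytest.raises(ValueError, match="without community"):
            bridge_metrics(net, {"V1": "a", "V2": "a", "V3": "b"})

    def test_removing_cross_edges_zeroes_bridge_strength(self, rng):
        comm = {f"V{i + 1}": ("a" if i < 3 else "b") for i in range(6)}
        net = random_network(rng, 6, density=0.8, communities=comm)
        labels = np.asarray([comm[v] for v in net.node_labels])
        cross = labels[:, None] != labels[None, :]
        W2 = np.where(cross, 0.0, net.weights)
        tab = bridge_metrics(_net(W2, comm))
        assert (tab["bridge_strength"] == 0).all()


class TestZStandardize:
    def test_closed_form_triple(self):
        np.testing.assert_allclose(z_standardize([1, 2, 3]), [-1, 0, 1])

    def test_constant_input_gives_zeros(self):
        assert np.all(z_standardize([5, 5, 5, 5]) == 0)

    def test_moments_of_output(self, rng):
        z = z_standardize(rng.normal(size=21))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestCentralityTable:
    def test_columns_and_z_pairing(self, rng):
        tab = centrality_table(random_network(rng, 6))
        for col in ("strength", "expected_influence", "closeness", "betweenness"):
            assert col in tab.columns
            assert f"z_{col}" in tab.columns

    def test_isolated_node_is_zero_everywhere(self, rng):
        net = random_network(rng, 5, density=0.9)
        W = net.weights.copy()
        W[0, :] = W[:, 0] = 0.0
        tab = centrality_table(_net(W))
        raw = tab.loc["V1", ["strength", "expected_influence", "closeness",
                             "betweenness"]]
        assert (raw == 0).all()


class TestLayout:
    def test_single_node_at_origin(self):
        layout = fruchterman_reingold(_net(np.zeros((1, 1))))
        assert layout.loc["V1"].tolist() == [0.0, 0.0]

    def test_two_nodes_symmetric_about_centroid(self):
        W = np.array([[0.0, 0.4], [0.4, 0.0]])
        layout = fruchterman_reingold(_net(W), seed=5)
        np.testing.assert_allclose(
            layout.loc["V1"].to_numpy(), -layout.loc["V2"].to_numpy(), atol=1e-9
        )

    def test_same_seed_same_coordinates(self, rng):
        net = random_network(rng, 8, density=0.4)
        l1 = fruchterman_reingold(net, seed=3)
        l2 = fruchterman_reingold(net, seed=3)
        pd.testing.assert_frame_equal(l1, l2)
        assert np.isfinite(l1.to_numpy()).all()
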