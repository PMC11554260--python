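import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trophnet.errors import JoinMismatchError
from trophnet.interactions import EdgeSet, build_network
from trophnet.metrics import (
    assemble_measures,
    betweenness_per_ant,
    degree_per_ant,
    density,
    total_distance,
    total_distances,
    walktrap_clusters,
)
from trophnet.simulate import TrialConfig, simulate_trial
from trophnet.studies import brute_force_betweenness
from trophnet.tracking import TrialMetadata, build_trajectories

from conftest import make_detections


def net_from_edges(pairs, roster=None, policy="participants"):
    nodes = sorted({a for p in pairs for a in p})
    return build_network(EdgeSet(pairs=pairs), roster=roster or nodes, policy=policy)


class TestDensity:
    def test_complete_graph(self):
        pairs = [(a, b) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
        assert density(net_from_edges(pairs)) == 1.0

    def test_path_of_four(self):
        assert density(net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])) == 0.5

    def test_edgeless_all_tagged(self):
        net = net_from_edges([], roster=list("abcde"), policy="all_tagged")
        assert density(net) == 0.0

    def test_fewer_than_two_nodes_warns_zero(self):
        with pytest.warns(UserWarning):
            assert density(net_from_edges([])) == 0.0

    def test_group_size_denominator_not_larger(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        assert (density(net, denominator="group_size", group_size=10)
                <= density(net))


class TestCentrality:
    def test_star_degrees(self):
        deg = degree_per_ant(net_from_edges([("c", x) for x in "abde"]))
        assert deg["c"] == 4 and all(deg[x] == 1 for x in "abde")

    def test_triangle_degrees(self):
        deg = degree_per_ant(net_from_edges([("a", "b"), ("b", "c"), ("a", "c")]))
        assert set(deg.values()) == {2}

    def test_path_betweenness(self):
        btw = betweenness_per_ant(net_from_edges([("a", "b"), ("b", "c")]))
        assert btw == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_center_betweenness(self):
        btw = betweenness_per_ant(net_from_edges([("c", x) for x in "abde"]))
        assert btw["c"] == pytest.approx(6.0)  # C(4,2) leaf pairs

    def test_complete_graph_betweenness_zero(self):
        pairs = [(a, b) for i, a in enumerate("abcde") for b in "abcde"[i + 1:]]
        assert all(v == 0.0 for v in betweenness_per_ant(net_from_edges(pairs)).values())

    def test_tree_betweenness_counts_pairs_through_node(self, rng):
        T = nx.random_labeled_tree(10, seed=4)
        T = nx.relabel_nodes(T, {v: f"a{v:02d}" for v in T.nodes()})
        net = net_from_edges([tuple(sorted(e)) for e in T.edges()])
        btw = betweenness_per_ant(net)
        oracle = brute_force_betweenness(net.graph)
        for v in oracle:
            assert btw[v] == pytest.approx(oracle[v], abs=1e-9)
            assert oracle[v] == pytest.approx(round(oracle[v]))  # unique paths in a tree

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10**6), n=st.integers(3, 10), p=st.floats(0.2, 0.8))
    def test_handshake_and_isolate_conventions(self, seed, n, p):
        G = nx.gnp_random_graph(n, p, seed=seed)
        G = nx.relabel_nodes(G, {v: f"a{v:02d}" for v in G.nodes()})
        net = net_from_edges([tuple(sorted(e)) for e in G.edges()],
                             roster=list(G.nodes()), policy="all_tagged")
        deg = degree_per_ant(net)
        assert sum(deg.values()) == 2 * net.n_edges
        btw = betweenness_per_ant(net)
        for v, d in deg.items():
            if d == 0:
                assert btw[v] == 0.0


class TestTotalDistance:
    def test_three_point_path(self):
        t = make_detections([(0, 0.0, "A", 0, 0, 0), (1, 1.0, "A", 3, 4, 0),
                             (2, 2.0, "A", 3, 4, 0)])
        assert total_distance(build_trajectories(t)["A"]) == pytest.approx(5.0)

    def test_single_point_zero(self):
        t = make_detections([(0, 0.0, "A", 7, 7, 0)])
        assert total_distance(build_trajectories(t)["A"]) == 0.0

    def test_frame_label_offset_irrelevant(self):
        rows = [(f, float(f), "A", f * 2.0, 0, 0) for f in range(5)]
        shifted = [(f + 100, float(f), "A", f * 2.0, 0, 0) for f in range(5)]
        d1 = total_distance(build_trajectories(make_detections(rows))["A"])
        d2 = total_distance(build_trajectories(make_detections(shifted))["A"])
        assert d1 == d2

    def test_rigid_motion_invariance(self, rng):
        rows = [(f, float(f), "A", float(rng.uniform(0, 100)),
                 float(rng.uniform(0, 100)), 0.0) for f in range(20)]
        d0 = total_distance(build_trajectories(make_detections(rows))["A"])
        phi, dx, dy = 1.2, 31.0, -8.0
        c, s = math.cos(phi), math.sin(phi)
        moved = [(f, t, a, c * x - s * y + dx, s * x + c * y + dy, th)
                 for (f, t, a, x, y, th) in rows]
        d1 = total_distance(build_trajectories(make_detections(moved))["A"])
        assert d1 == pytest.approx(d0, rel=1e-12)

    def test_simulator_path_length_oracle(self):
        # sampling at the fine-grid rate captures every step exactly
        cfg = TrialConfig(group_size=6, duration_s=200.0, frame_rates=(1.0,),
                          n_planted_pairs=1, seed=6)
        table, _, truth = simulate_trial(cfg)
        dists = total_distances(build_trajectories(table))
        for ant, true_len in truth.path_length_px.items():
            assert dists[ant] == pytest.approx(true_len, rel=1e-3)
        # subsampling can only shorten the recorded path
        cfg2 = TrialConfig(group_size=6, duration_s=200.0, frame_rates=(0.31,),
                           n_planted_pairs=1, seed=6)
        table2, _, truth2 = simulate_trial(cfg2)
        dists2 = total_distances(build_trajectories(table2))
        for ant, true_len in truth2.path_length_px.items():
            assert dists2[ant] <= true_len + 1e-9


class TestWalktrapWrapper:
    def test_membership_and_count(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                              ("x", "y"), ("y", "z"), ("x", "z")])
        membership, k = walktrap_clusters(net)
        assert k == 2
        assert membership["a"] == membership["b"] == membership["c"]
        assert membership["x"] != membership["a"]


class TestAssemble:
    def _trial(self, trial_id, group_id, seed):
        t = make_detections([
            (0, 0.0, "a", 0, 0, 0), (0, 0.0, "b", 10, 0, 0),
            (1, 1.0, "b", 10, 0, 0), (1, 1.0, "c", 15, 0, 0),
        ], trial_id=trial_id)
        traj = build_trajectories(t)
        traj.trial_id = trial_id
        net = net_from_edges([("a", "b"), ("b", "c")])
        net.trial_id = trial_id
        meta = TrialMetadata(trial_id=trial_id, group_id=group_id, group_size=5,
                             food_type="carbohydrate", food_availability="limited",
                             mean_frame_rate_ips=1.0)
        return net, traj, meta

    def test_row_counts_and_no_isolates(self):
        items = [self._trial("T1", "G1", 0), self._trial("T2", "G2", 1)]
        g, i = assemble_measures(*map(list, zip(*items)))
        assert len(g) == 2
        assert len(i) == 6  # three participants per trial
        assert (i["degree"] >= 1).all()
        assert set(i["individual_id"]) == {f"G{k}:{a}" for k in (1, 2) for a in "abc"}

    def test_join_mismatch(self):
        n1, t1, m1 = self._trial("T1", "G1", 0)
        _, _, m2 = self._trial("T2", "G2", 1)
        with pytest.raises(JoinMismatchError):
            assemble_measures([n1], [t1], [m2])
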