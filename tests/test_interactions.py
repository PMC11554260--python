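import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trophnet.errors import (
    EmptyMeasurementsError,
    InconsistentRosterError,
    UnknownAntError,
)
from trophnet.interactions import (
    EdgeSet,
    InteractionDetector,
    build_network,
    calibrate_threshold,
    detect_interactions,
    participation_proportion,
)
from trophnet.studies import brute_force_edges
from trophnet.tracking import build_trajectories

from conftest import make_detections


class TestCalibration:
    def test_highest_per_trial_mean_wins(self):
        cal = calibrate_threshold({"A": [100, 104], "B": [90]}, target_frames=1)
        assert cal.threshold_px == pytest.approx(102.0)
        assert cal.per_trial_mean_px == {"A": 102.0, "B": 90.0}

    def test_single_trial(self):
        assert calibrate_threshold({"A": [50, 50, 50]},
                                   target_frames=3).threshold_px == 50.0

    def test_reference_operating_value(self):
        """Three trials with means 80 < 95 < 102 give the 102 px threshold."""
        measurements = {
            "t1": [80.0] * 50,
            "t2": [95.0] * 50,
            "t3": [100.0, 104.0] * 25,
        }
        assert calibrate_threshold(measurements).threshold_px == pytest.approx(102.0)

    def test_undersampled_trial_warns(self):
        with pytest.warns(UserWarning, match="sampled frames"):
            calibrate_threshold({"A": [10.0] * 10})

    def test_empty_measurements_error(self):
        with pytest.raises(EmptyMeasurementsError):
            calibrate_threshold({"A": []})
        with pytest.raises(EmptyMeasurementsError):
            calibrate_threshold({})


class TestDetect:
    def test_boundary_inclusive_at_threshold(self, two_ant_frame):
        edges = detect_interactions(build_trajectories(two_ant_frame(102.0)), 102.0)
        assert ("a00", "a01") in edges

    def test_just_beyond_threshold_excluded(self, two_ant_frame):
        edges = detect_interactions(build_trajectories(two_ant_frame(102.1)), 102.0)
        assert len(edges) == 0

    def test_three_mutually_close_ants_three_edges(self):
        t = make_detections([(0, 0.0, "a", 0, 0, 0), (0, 0.0, "b", 10, 0, 0),
                             (0, 0.0, "c", 5, 8, 0)])
        assert len(detect_interactions(build_trajectories(t), 102.0)) == 3

    def test_codetection_required(self):
        # same spot but never in the same frame
        t = make_detections([(0, 0.0, "a", 0, 0, 0), (1, 1.0, "b", 0, 0, 0)])
        assert len(detect_interactions(build_trajectories(t), 102.0)) == 0

    def test_repeated_contacts_single_edge_and_first_frame(self):
        t = make_detections([
            (0, 0.0, "a", 0, 0, 0), (0, 0.0, "b", 500, 0, 0),
            (3, 1.0, "a", 0, 0, 0), (3, 1.0, "b", 50, 0, 0),
            (5, 2.0, "a", 0, 0, 0), (5, 2.0, "b", 40, 0, 0),
        ])
        edges = detect_interactions(build_trajectories(t), 102.0)
        assert edges.pairs == [("a", "b")]
        assert edges.first_contact[("a", "b")] == 3

    def test_head_offset_changes_detection(self):
        # tags 110 px apart, facing each other: heads 10 px closer each
        t = make_detections([(0, 0.0, "a", 0, 0, 0.0),
                             (0, 0.0, "b", 110.0, 0, math.pi)])
        far = detect_interactions(build_trajectories(t, head_offset_px=0.0), 102.0)
        near = detect_interactions(build_trajectories(t, head_offset_px=10.0), 102.0)
        assert len(far) == 0 and len(near) == 1

    @settings(deadline=None, max_examples=30)
    @given(st.data())
    def test_monotone_in_threshold_and_matches_bruteforce(self, data):
        n_ants = data.draw(st.integers(2, 5))
        n_frames = data.draw(st.integers(1, 10))
        coords = data.draw(st.lists(
            st.tuples(st.floats(0, 300), st.floats(0, 300)),
            min_size=n_ants * n_frames, max_size=n_ants * n_frames))
        rows = []
        it = iter(coords)
        for f in range(n_frames):
            for a in range(n_ants):
                x, y = next(it)
                rows.append((f, float(f), f"a{a:02d}", x, y, 0.0))
        traj = build_trajectories(make_detections(rows))
        t1 = data.draw(st.floats(10, 150))
        t2 = data.draw(st.floats(10, 150))
        lo, hi = sorted((t1, t2))
        e_lo = detect_interactions(traj, lo).as_set()
        e_hi = detect_interactions(traj, hi).as_set()
        assert e_lo <= e_hi
        assert e_hi == brute_force_edges(traj, hi)

    def test_rigid_motion_and_relabel_invariance(self, rng):
        rows = [(f, float(f), f"a{a:02d}",
                 float(rng.uniform(0, 400)), float(rng.uniform(0, 400)), 0.0)
                for f in range(8) for a in range(5)]
        base = detect_interactions(build_trajectories(make_detections(rows)), 102.0)
        phi, dx, dy = 0.9, 55.0, -40.0
        c, s = math.cos(phi), math.sin(phi)
        moved = [(f, t, a, c * x - s * y + dx, s * x + c * y + dy, th)
                 for (f, t, a, x, y, th) in rows]
        rot = detect_interactions(build_trajectories(make_detections(moved)), 102.0)
        assert base.as_set() == rot.as_set()
        relabeled = [(f, t, {"a00": "z", "a01": "y", "a02": "x", "a03": "w",
                             "a04": "v"}[a], x, y, th)
                     for (f, t, a, x, y, th) in rows]
        rel = detect_interactions(build_trajectories(make_detections(relabeled)), 102.0)
        mapping = {"a00": "z", "a01": "y", "a02": "x", "a03": "w", "a04": "v"}
        assert rel.as_set() == {tuple(sorted((mapping[a], mapping[b])))
                                for a, b in base.as_set()}


class TestBuildNetwork:
    def test_participants_policy(self):
        net = build_network(EdgeSet(pairs=[("1", "2")]),
                            roster=["1", "2", "3", "4", "5"])
        assert (net.n_nodes, net.n_edges) == (2, 1)

    def test_all_tagged_policy_keeps_isolates(self):
        net = build_network(EdgeSet(pairs=[("1", "2")]),
                            roster=["1", "2", "3", "4", "5"], policy="all_tagged")
        assert (net.n_nodes, net.n_edges) == (5, 1)
        assert net.graph.nodes["3"]["participant"] is False

    def test_no_edges_participants_empty_graph(self):
        net = build_network(EdgeSet(pairs=[]), roster=["1", "2"])
        assert net.n_nodes == 0

    def test_unknown_ant_rejected(self):
        with pytest.raises(UnknownAntError):
            build_network(EdgeSet(pairs=[("1", "9")]), roster=["1", "2"])


class TestParticipation:
    @pytest.mark.parametrize("pairs,roster,group_size,expected", [
        ([(f"a{i}", f"b{i}") for i in range(7)], None, 14, 1.0),
        ([("a0", "a1"), ("a2", "a3")] + [(f"a{i}", f"a{i+1}") for i in range(4, 14)],
         None, 20, None),  # computed below
        ([], ["x", "y"], 5, 0.0),
    ])
    def test_examples(self, pairs, roster, group_size, expected):
        nodes = sorted({a for p in pairs for a in p})
        net = build_network(EdgeSet(pairs=pairs), roster=roster or nodes)
        got = participation_proportion(net, group_size)
        if expected is None:
            expected = len(nodes) / group_size
        assert got == pytest.approx(expected)

    def test_inconsistent_roster(self):
        net = build_network(EdgeSet(pairs=[("a", "b"), ("c", "d")]),
                            roster=["a", "b", "c", "d"])
        with pytest.raises(InconsistentRosterError):
            participation_proportion(net, 3)


class TestDetectorEstimator:
    def test_fit_exposes_network_and_params_roundtrip(self, two_ant_frame):
        det = InteractionDetector(threshold_px=102.0)
        assert det.get_params()["threshold_px"] == 102.0
        det.set_params(threshold_px=50.0)
        det.fit(two_ant_frame(60.0))
        assert det.n_edges_ == 0
        det.set_params(threshold_px=102.0).fit(two_ant_frame(60.0))
        assert det.n_edges_ == 1
        assert det.participation_ == 1.0
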