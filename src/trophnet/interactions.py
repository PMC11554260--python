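"""Threshold calibration and head-to-head interaction networks.

Two ants are considered to have interacted (a potential trophallaxis event)
if their head points were *equal to or less than* a threshold distance apart
in at least one frame where both were detected.  Edges are binary — frame
rates vary across and within trials, so durations are deliberately discarded —
and the resulting network is simple, undirected and unweighted.

The operating threshold is calibrated from manual head-to-head distance
measurements: the per-trial means are computed and the *highest* per-trial
mean across trials becomes the single threshold applied everywhere
(102 px at 0.04 mm/px for the reference setup).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import EmptyMeasurementsError, InconsistentRosterError, UnknownAntError
from .tracking import DetectionTable, TrajectorySet, build_trajectories

DEFAULT_THRESHOLD_PX = 102.0
CALIBRATION_TARGET_FRAMES = 50


@dataclass(frozen=True)
class ThresholdCalibration:
    """Per-trial mean manual distances and their maximum (the threshold)."""

    per_trial_mean_px: dict[str, float]
    n_sampled: dict[str, int]
    threshold_px: float


def calibrate_threshold(
    measurements: Mapping[str, Sequence[float]],
    target_frames: int = CALIBRATION_TARGET_FRAMES,
) -> ThresholdCalibration:
    """Calibrate the proximity threshold from manual measurements.

    ``measurements`` maps trial id -> manually measured head-to-head distances
    (px), one per sampled frame.  The threshold is the maximum over trials of
    the per-trial mean.  A warning is emitted for any trial sampled fewer than
    ``target_frames`` times.
    """
    if not measurements:
        raise EmptyMeasurementsError("no trials to calibrate from")
    means, counts = {}, {}
    for trial, vals in measurements.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size == 0:
            raise EmptyMeasurementsError(f"trial {trial!r} has no measurements")
        if not (vals > 0).all():
            raise ValueError(f"trial {trial!r}: distances must be positive")
        if vals.size < target_frames:
            warnings.warn(
                f"trial {trial!r}: only {vals.size} sampled frames "
                f"(target {target_frames})", stacklevel=2,
            )
        means[str(trial)] = float(vals.mean())
        counts[str(trial)] = int(vals.size)
    return ThresholdCalibration(
        per_trial_mean_px=means, n_sampled=counts,
        threshold_px=max(means.values()),
    )


@dataclass
class EdgeSet:
    """Unordered interacting ant pairs with first-contact frame (diagnostic)."""

    pairs: list[tuple[str, str]]
    first_contact: dict[tuple[str, str], int] = field(default_factory=dict)
    trial_id: str | None = None

    def __post_init__(self):
        canon = []
        seen = set()
        for (a, b) in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            p = (a, b) if a <= b else (b, a)
            if p not in seen:
                seen.add(p)
                canon.append(p)
        self.pairs = sorted(canon)
        self.first_contact = {
            ((a, b) if a <= b else (b, a)): f for (a, b), f in self.first_contact.items()
        }

    def __contains__(self, pair) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in set(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def as_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "ant_i": [p[0] for p in self.pairs],
                "ant_j": [p[1] for p in self.pairs],
                "first_contact_frame": [self.first_contact.get(p, -1) for p in self.pairs],
            }
        )


def detect_interactions(
    traj: TrajectorySet, threshold_px: float = DEFAULT_THRESHOLD_PX,
    chunk_frames: int = 2048,
) -> EdgeSet:
    """Pairs whose heads came within ``threshold_px`` in any co-detected frame.

    The boundary is inclusive (distance == threshold counts).  A frame
    contributes only if *both* ants are detected in it, so missed detections
    can never create an edge.  Each pair appears at most once regardless of
    how many contacts occurred.
    """
    if threshold_px <= 0:
        raise ValueError("threshold_px must be > 0")
    frames, ants, heads = traj.head_panel()
    n = len(ants)
    contact = np.zeros((n, n), dtype=bool)
    first = np.full((n, n), -1, dtype=int)
    for lo in range(0, len(frames), chunk_frames):
        h = heads[lo:lo + chunk_frames]                       # (f, n, 2)
        diff = h[:, :, None, :] - h[:, None, :, :]
        dist = np.linalg.norm(diff, axis=-1)                  # NaN unless co-detected
        with np.errstate(invalid="ignore"):
            hit = dist <= threshold_px
        any_hit = hit.any(axis=0)
        new = any_hit & ~contact
        if new.any():
            firsts = hit.argmax(axis=0)                       # first frame in chunk
            ii, jj = np.nonzero(new)
            first[ii, jj] = frames[lo + firsts[ii, jj]]
        contact |= any_hit
    iu = np.triu_indices(n, k=1)
    pairs, fc = [], {}
    for i, j in zip(*iu):
        if contact[i, j]:
            p = (ants[i], ants[j])
            pairs.append(p)
            fc[p] = int(first[i, j])
    return EdgeSet(pairs=pairs, first_contact=fc, trial_id=traj.trial_id)


@dataclass
class InteractionNetwork:
    """Simple undirected unweighted graph of ants that interacted.

    Under the default ``participants`` node policy the node set is exactly the
    ants incident to at least one edge (interaction networks may include fewer
    individuals than the group); under ``all_tagged`` the full roster is kept
    and isolates carry ``participant=False``.
    """

    graph: nx.Graph
    policy: str
    roster: tuple[str, ...]
    trial_id: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def participants(self) -> list[str]:
        return sorted(n for n, d in self.graph.degree() if d > 0)


def build_network(
    edges: EdgeSet, roster: Iterable[str], policy: str = "participants",
) -> InteractionNetwork:
    """Assemble the interaction network from an edge set and the trial roster."""
    if policy not in ("participants", "all_tagged"):
        raise ValueError(f"unknown node policy {policy!r}")
    roster = tuple(sorted(str(a) for a in roster))
    roster_set = set(roster)
    for (a, b) in edges.pairs:
        if a not in roster_set or b not in roster_set:
            raise UnknownAntError(f"edge endpoint not on roster: {(a, b)}")
    g = nx.Graph()
    if policy == "all_tagged":
        g.add_nodes_from(roster)
    g.add_edges_from(edges.pairs)
    participants = {n for n, d in g.degree() if d > 0}
    nx.set_node_attributes(g, {n: (n in participants) for n in g.nodes}, "participant")
    return InteractionNetwork(graph=g, policy=policy, roster=roster, trial_id=edges.trial_id)


def participation_proportion(net: InteractionNetwork, group_size: int) -> float:
    """Fraction of tagged ants that participated in the network."""
    k = len(net.participants)
    if k > group_size:
        raise InconsistentRosterError(
            f"{k} participants exceed group size {group_size}"
        )
    return k / group_size if group_size else 0.0


class InteractionDetector(BaseEstimator):
    """Estimator wrapper: detections -> head trajectories -> interaction network.

    Parameters mirror the inference stage: proximity threshold (px), tag-to-head
    offset (px) and node policy.  After :meth:`fit`, the edge set, network and
    participation proportion are available as fitted attributes.
    """

    def __init__(self, threshold_px: float = DEFAULT_THRESHOLD_PX,
                 head_offset_px: float = 0.0, node_policy: str = "participants"):
        self.threshold_px = threshold_px
        self.head_offset_px = head_offset_px
        self.node_policy = node_policy

    def fit(self, detections: DetectionTable, roster: Iterable[str] | None = None):
        traj = build_trajectories(detections, head_offset_px=self.head_offset_px)
        self.trajectories_ = traj
        self.edges_ = detect_interactions(traj, threshold_px=self.threshold_px)
        roster = list(roster) if roster is not None else detections.ants
        self.network_ = build_network(self.edges_, roster, policy=self.node_policy)
        self.n_edges_ = len(self.edges_)
        self.participation_ = participation_proportion(self.network_, len(roster))
        return self

    def fit_predict(self, detections: DetectionTable,
                    roster: Iterable[str] | None = None) -> EdgeSet:
        return self.fit(detections, roster=roster).edges_


def write_edge_list(edges: EdgeSet, path: str | Path) -> Path:
    path = Path(path)
    edges.to_frame().to_csv(path, index=False)
    return path


def write_graphml(net: InteractionNetwork, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(net.graph, path)
    return path
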