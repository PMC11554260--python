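"""Network and activity measures.

Global measures per trial: network *density* (observed edges over all
possible pairs) and the *number of clusters* found by walktrap.  Individual
measures per ant: *degree* (number of distinct interaction partners),
*betweenness* (sum over node pairs of the fraction of their shortest paths
passing through the focal ant, unnormalised, each unordered pair counted
once, unreachable pairs contributing zero) and *total distance moved* (sum of
Euclidean step lengths between consecutive detections, pixels).
"""

from __future__ import annotations

import warnings
from math import comb
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import JoinMismatchError
from .interactions import InteractionNetwork
from .tracking import Trajectory, TrajectorySet, TrialMetadata
from .walktrap import DEFAULT_STEPS, walktrap_communities


def density(net: InteractionNetwork, denominator: str = "nodes",
            group_size: int | None = None) -> float:
    """Edges divided by all possible pairs.

    ``denominator="nodes"`` uses the constructed graph's node set (with the
    default participants policy this is the edge-list convention);
    ``denominator="group_size"`` uses C(group_size, 2) over all tagged ants.
    """
    e = net.n_edges
    if denominator == "group_size":
        if group_size is None:
            raise ValueError("group_size required for denominator='group_size'")
        n = group_size
    elif denominator == "nodes":
        n = net.n_nodes
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if n < 2:
        warnings.warn("density undefined for < 2 nodes; returning 0.0", stacklevel=2)
        return 0.0
    return e / comb(n, 2)


def degree_per_ant(net: InteractionNetwork) -> dict[str, int]:
    """Number of unique interaction partners per ant (binary network)."""
    return {n: int(d) for n, d in net.graph.degree()}


def betweenness_per_ant(net: InteractionNetwork) -> dict[str, float]:
    """Unnormalised shortest-path betweenness per ant.

    Fractional over multiple shortest paths; each unordered pair counted once;
    isolated nodes (all_tagged policy) have betweenness 0 by convention.
    """
    return {
        n: float(b)
        for n, b in nx.betweenness_centrality(net.graph, normalized=False).items()
    }


def walktrap_clusters(net: InteractionNetwork, steps: int = DEFAULT_STEPS,
                      ) -> tuple[dict[str, int], int]:
    """Walktrap membership and cluster count at the maximum-modularity cut."""
    res = walktrap_communities(net.graph, steps=steps)
    return res.membership, res.n_clusters


def total_distance(traj: Trajectory) -> float:
    """Total distance moved (px): summed consecutive-detection step lengths."""
    if len(traj) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(traj.xy, axis=0), axis=1).sum())


def total_distances(trajset: TrajectorySet) -> dict[str, float]:
    return {a: total_distance(t) for a, t in sorted(trajset.trajectories.items())}


def assemble_measures(
    networks: Sequence[InteractionNetwork],
    trajectories: Sequence[TrajectorySet],
    metadata: Sequence[TrialMetadata],
    steps: int = DEFAULT_STEPS,
    density_denominator: str = "nodes",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join networks, activity and treatment metadata into the analysis tables.

    Returns ``(global_df, individual_df)``: one row per trial with density and
    cluster count; one row per *participant* ant with degree, betweenness and
    total distance.  Individuals are keyed ``group_id:ant_id`` so that ants of
    a group retested across trials are treated as repeated measures.
    """
    ids = [n.trial_id for n in networks]
    if not (ids == [t.trial_id for t in trajectories] == [m.trial_id for m in metadata]):
        raise JoinMismatchError("trial identifiers do not align across inputs")
    g_rows, i_rows = [], []
    for net, trajset, meta in zip(networks, trajectories, metadata):
        membership, n_clusters = walktrap_clusters(net, steps=steps)
        deg = degree_per_ant(net)
        btw = betweenness_per_ant(net)
        dist = total_distances(trajset)
        common = {
            "trial_id": meta.trial_id,
            "group_id": meta.group_id,
            "group_size": meta.group_size,
            "food_type": meta.food_type,
            "food_availability": meta.food_availability,
            "mean_frame_rate_ips": meta.mean_frame_rate_ips,
        }
        g_rows.append({
            **common,
            "density": density(net, denominator=density_denominator,
                               group_size=meta.group_size),
            "n_clusters": n_clusters,
            "n_participants": len(net.participants),
            "participation": len(net.participants) / meta.group_size,
        })
        for ant in net.participants:
            i_rows.append({
                **common,
                "ant_id": ant,
                "individual_id": f"{meta.group_id}:{ant}",
                "degree": deg[ant],
                "betweenness": btw[ant],
                "total_distance_px": dist.get(ant, 0.0),
            })
    return pd.DataFrame(g_rows), pd.DataFrame(i_rows)
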