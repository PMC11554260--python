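"""Random-walk agglomerative community detection (walktrap).

Implements the published walktrap algorithm: the probability distribution of a
short random walk (default 4 steps) started at a node characterises its
community; communities are merged greedily, always joining the *adjacent*
pair whose merger least increases the mean squared walk-distance between
nodes and their community (Ward-style criterion), and the resulting merge
dendrogram is cut at the partition of maximum modularity.

Definitions, for a graph with n walk-active (non-isolated) nodes, adjacency A
and degrees d (the walk itself is made lazy by adding a self-loop to every
vertex, as the reference implementation does, so A below is A + I and d is
the corresponding degree; modularity is always evaluated on the original
graph):

* transition matrix ``P = D^-1 A`` and its t-step power ``P^t``;
* community distribution ``P^t_C = mean over members of P^t_i``;
* squared distance ``r^2(C1, C2) = sum_k (P^t_{C1 k} - P^t_{C2 k})^2 / d_k``;
* merge cost ``delta_sigma(C1, C2) = (1/n) * |C1||C2|/(|C1|+|C2|) * r^2``.

Only communities sharing at least one edge may merge, so disconnected
components never join; isolated nodes take no part in the walk and each
counts as its own community in the final partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

DEFAULT_STEPS = 4


@dataclass
class WalktrapResult:
    membership: dict          # node -> community label (0..k-1)
    n_clusters: int
    modularity: float         # at the chosen cut (walk-active subgraph)
    merge_modularities: np.ndarray  # modularity at every dendrogram level


def _modularity(partition_of: np.ndarray, A: np.ndarray, d: np.ndarray, m: float) -> float:
    """Newman modularity of a labelled partition of the walk-active subgraph."""
    q = 0.0
    for c in np.unique(partition_of):
        mask = partition_of == c
        lc = A[np.ix_(mask, mask)].sum() / 2.0
        dc = d[mask].sum()
        q += lc / m - (dc / (2.0 * m)) ** 2
    return q


def walktrap_communities(graph: nx.Graph, steps: int = DEFAULT_STEPS) -> WalktrapResult:
    """Run walktrap and cut the dendrogram at maximum modularity."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    nodes = sorted(graph.nodes())
    if not nodes:
        return WalktrapResult({}, 0, 0.0, np.empty(0))
    isolates = [v for v in nodes if graph.degree(v) == 0]
    active = [v for v in nodes if graph.degree(v) > 0]
    if not active:
        membership = {v: i for i, v in enumerate(nodes)}
        return WalktrapResult(membership, len(nodes), 0.0, np.empty(0))

    A0 = nx.to_numpy_array(graph, nodelist=active)
    n = len(active)
    d0 = A0.sum(axis=1)
    m = d0.sum() / 2.0
    # the reference implementation walks a *lazy* chain: every vertex gets a
    # self-loop, which guarantees aperiodicity of the walk
    A = A0 + np.eye(n)
    d = A.sum(axis=1)
    P = A / d[:, None]
    Pt = np.linalg.matrix_power(P, steps)

    # community state
    comm = {i: [i] for i in range(n)}          # community id -> member indices
    size = {i: 1 for i in range(n)}
    pvec = {i: Pt[i].copy() for i in range(n)}
    label = np.arange(n)                        # node index -> community id
    adj: set[tuple[int, int]] = set()
    for i, j in zip(*np.nonzero(np.triu(A0, k=1))):
        adj.add((int(i), int(j)))

    inv_d = 1.0 / d
    levels = [label.copy()]
    next_id = n
    while adj:
        best, best_ds = None, np.inf
        for (c1, c2) in sorted(adj):
            diff = pvec[c1] - pvec[c2]
            r2 = float(np.sum(diff * diff * inv_d))
            ds = (size[c1] * size[c2]) / (size[c1] + size[c2]) * r2 / n
            if ds < best_ds - 1e-15:
                best, best_ds = (c1, c2), ds
        c1, c2 = best
        new = next_id
        next_id += 1
        comm[new] = comm.pop(c1) + comm.pop(c2)
        size[new] = size.pop(c1) + size.pop(c2)
        pvec[new] = (Pt[comm[new]].sum(axis=0)) / size[new]
        pvec.pop(c1, None), pvec.pop(c2, None)
        label = label.copy()
        label[np.isin(label, (c1, c2))] = new
        levels.append(label)
        adj = {
            tuple(sorted((new if a in (c1, c2) else a, new if b in (c1, c2) else b)))
            for (a, b) in adj
        }
        adj = {(a, b) for (a, b) in adj if a != b}

    mods = np.array([_modularity(lv, A0, d0, m) for lv in levels])
    cut = int(np.argmax(mods))
    chosen = levels[cut]
    # relabel communities 0..k-1 in order of smallest member node
    order = {}
    for idx in np.argsort(chosen, kind="stable"):
        order.setdefault(int(chosen[idx]), None)
    first_member = {c: min(i for i in range(n) if chosen[i] == c) for c in set(chosen.tolist())}
    ranked = sorted(first_member, key=lambda c: first_member[c])
    relabel = {c: k for k, c in enumerate(ranked)}
    membership = {active[i]: relabel[int(chosen[i])] for i in range(n)}
    k = len(ranked)
    for v in isolates:
        membership[v] = k
        k += 1
    return WalktrapResult(
        membership=membership, n_clusters=k,
        modularity=float(mods[cut]), merge_modularities=mods,
    )


class WalktrapClustering(BaseEstimator, ClusterMixin):
    """Clustering-estimator interface to :func:`walktrap_communities`.

    ``fit(G)`` accepts a networkx graph; fitted attributes are ``labels_``
    (array aligned with ``nodes_``, the sorted node list), ``membership_``
    (node -> label) and ``n_clusters_``.
    """

    def __init__(self, steps: int = DEFAULT_STEPS):
        self.steps = steps

    def fit(self, G: nx.Graph, y=None):
        res = walktrap_communities(G, steps=self.steps)
        self.nodes_ = sorted(G.nodes())
        self.membership_ = res.membership
        self.labels_ = np.array([res.membership[v] for v in self.nodes_], dtype=int)
        self.n_clusters_ = res.n_clusters
        self.modularity_ = res.modularity
        return self

    def fit_predict(self, G: nx.Graph, y=None):
        return self.fit(G).labels_
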