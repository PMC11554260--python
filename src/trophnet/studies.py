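"""Validation studies: recovery, oracle-agreement and calibration harnesses.

Each study regenerates its inputs from a seed, runs the package's own
implementation, and measures agreement with an independent route — planted
simulator ground truth, exhaustive brute-force enumeration, an external
reference implementation, or the known sampling distribution.  The studies
back both the test suite and the reproduction script, so their problem sizes
are chosen to run on a single CPU in minutes; sizes are parameters, not
constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as st

from .design import ModelSpec, candidate_specs
from .inference import MixedModel, emm_contrasts, select_model_aic
from .interactions import EdgeSet, build_network, detect_interactions
from .metrics import betweenness_per_ant, degree_per_ant
from .simulate import EffectConfig, TrialConfig, simulate_measures, simulate_trial
from .tracking import build_trajectories
from .walktrap import walktrap_communities


# --- brute-force oracles -----------------------------------------------------

def brute_force_edges(traj, threshold_px: float) -> set[tuple[str, str]]:
    """Pairwise per-frame distance enumeration, the slow way."""
    frames, ants, heads = traj.head_panel()
    out = set()
    for i, j in combinations(range(len(ants)), 2):
        for f in range(len(frames)):
            a, b = heads[f, i], heads[f, j]
            if np.isnan(a).any() or np.isnan(b).any():
                continue
            if math.dist(a, b) <= threshold_px:
                out.add((ants[i], ants[j]))
                break
    return out


def brute_force_betweenness(G: nx.Graph) -> dict:
    """Exhaustive shortest-path enumeration (bounded DFS per node pair)."""
    nodes = sorted(G.nodes())
    btw = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        try:
            d = nx.shortest_path_length(G, s, t)
        except nx.NetworkXNoPath:
            continue
        paths = []

        def dfs(v, path):
            if len(path) - 1 > d:
                return
            if v == t and len(path) - 1 == d:
                paths.append(list(path))
                return
            for w in G[v]:
                if w not in path:
                    path.append(w)
                    dfs(w, path)
                    path.pop()

        dfs(s, [s])
        if not paths:
            continue
        sigma = len(paths)
        for p in paths:
            for v in p[1:-1]:
                btw[v] += 1.0 / sigma
    return btw


# --- validation studies ------------------------------------------------------

@dataclass
class RecoveryStudy:
    n_trials: int
    n_pairs_total: int
    false_positives: int
    false_negatives: int
    min_margin_px: float


def interaction_recovery_study(
    n_trials: int = 20, seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    duration_s: float = 600.0, threshold_px: float = 102.0,
) -> RecoveryStudy:
    """Noiseless ground-truth recovery of planted interaction pairs.

    Per seed, ``n_trials`` trials with group sizes spanning 14-30, base frame
    rates spanning the full 0.31-2.92 images/s range, and 3-10 planted pairs
    each; the detector at 102 px must return exactly the planted edge sets.
    """
    fp = fn = pairs_total = trials_total = 0
    min_margin = np.inf
    for seed in seeds:
        rng = np.random.default_rng(seed)
        for t in range(n_trials):
            size = 14 + int(round((30 - 14) * t / max(n_trials - 1, 1)))
            base_rate = 0.31 + (2.92 - 0.31) * t / max(n_trials - 1, 1)
            rates = tuple(float(np.clip(base_rate + dr, 0.31, 2.92))
                          for dr in rng.uniform(-0.3, 0.3, size=3))
            k = int(rng.integers(3, min(10, size // 2) + 1))
            cfg = TrialConfig(
                trial_id=f"S{seed}T{t:02d}", group_size=size,
                duration_s=duration_s, frame_rates=rates,
                n_planted_pairs=k, threshold_px=threshold_px,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            table, meta, truth = simulate_trial(cfg)
            traj = build_trajectories(table)
            found = detect_interactions(traj, threshold_px=threshold_px).as_set()
            fp += len(found - truth.interacting_pairs)
            fn += len(truth.interacting_pairs - found)
            pairs_total += len(truth.interacting_pairs)
            trials_total += 1
            min_margin = min(min_margin, truth.non_interacting_margin_px)
    return RecoveryStudy(
        n_trials=trials_total, n_pairs_total=pairs_total,
        false_positives=fp, false_negatives=fn,
        min_margin_px=float(min_margin),
    )


@dataclass
class CentralityStudy:
    n_graphs: int
    max_betweenness_abs_err: float
    degree_mismatches: int


def centrality_oracle_study(n_graphs: int = 200, seed: int = 0,
                            max_nodes: int = 12) -> CentralityStudy:
    """Degree and betweenness versus exhaustive brute-force enumeration."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    deg_bad = 0
    done = 0
    while done < n_graphs:
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.15, 0.7))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        if G.number_of_edges() == 0:
            continue
        done += 1
        G = nx.relabel_nodes(G, {v: f"a{v:02d}" for v in G.nodes()})
        edges = EdgeSet(pairs=[tuple(sorted(e)) for e in G.edges()])
        net = build_network(edges, roster=list(G.nodes()), policy="all_tagged")
        btw = betweenness_per_ant(net)
        deg = degree_per_ant(net)
        oracle = brute_force_betweenness(net.graph)
        worst = max(worst, max(abs(btw[v] - oracle[v]) for v in oracle))
        for v in net.graph.nodes():
            if deg[v] != len(set(net.graph[v])):
                deg_bad += 1
    return CentralityStudy(n_graphs=done, max_betweenness_abs_err=float(worst),
                           degree_mismatches=deg_bad)


@dataclass
class WalktrapStudy:
    n_graphs: int
    n_agree: int
    fixture_counts: dict


def _igraph_walktrap_count(G: nx.Graph, steps: int = 4) -> int:
    import igraph as ig

    nodes = sorted(G.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(idx[a], idx[b]) for a, b in G.edges()])
    return len(g.community_walktrap(steps=steps).as_clustering())


def planted_partition_graph(rng: np.random.Generator) -> nx.Graph:
    """A small graph with 2-4 planted communities (tie-free walktrap input)."""
    k = int(rng.integers(2, 5))
    sizes = [int(rng.integers(4, 9)) for _ in range(k)]
    p_in = float(rng.uniform(0.6, 0.9))
    p_out = float(rng.uniform(0.02, 0.10))
    probs = [[p_in if i == j else p_out for j in range(k)] for i in range(k)]
    G = nx.Graph(nx.stochastic_block_model(
        sizes, probs, seed=int(rng.integers(0, 2**31 - 1))))
    G.remove_nodes_from(list(nx.isolates(G)))
    return G


def walktrap_agreement_study(n_graphs: int = 50, seed: int = 0,
                             steps: int = 4) -> WalktrapStudy:
    """Cluster-count agreement with the igraph reference implementation."""
    rng = np.random.default_rng(seed)
    agree = 0
    done = 0
    while done < n_graphs:
        G = planted_partition_graph(rng)
        if G.number_of_nodes() < 2 or G.number_of_edges() < 1 or G.number_of_nodes() > 30:
            continue
        done += 1
        if walktrap_communities(G, steps=steps).n_clusters == _igraph_walktrap_count(G, steps):
            agree += 1
    fixtures = {
        "two_triangles": walktrap_communities(
            nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))).n_clusters,
        "K6": walktrap_communities(nx.complete_graph(6)).n_clusters,
        "barbell_K5": walktrap_communities(nx.barbell_graph(5, 0)).n_clusters,
    }
    return WalktrapStudy(n_graphs=done, n_agree=agree, fixture_counts=fixtures)


RECOVERY_SPEC = ModelSpec(
    response="degree_like", interaction="type_availability",
    random_effects=("group_id", "individual_id"),
)

TRUE_BETAS = {
    "group_size": "beta_group_size",
    "food_type[carbohydrate]": "beta_food_type",
    "food_availability[unlimited]": "beta_availability",
    "food_type:food_availability": "beta_interaction",
}


@dataclass
class LmmRecoveryStudy:
    n_replicates: int
    mean_estimates: dict
    true_values: dict
    coverage: dict
    mean_carb_contrast: float
    contrast_se_mc: float


def lmm_recovery_study(n_replicates: int = 500, seed: int = 0,
                       cfg: EffectConfig | None = None) -> LmmRecoveryStudy:
    """Fixed-effect recovery, CI coverage and EMM-contrast recovery.

    Generates measure tables at the reference conditions (40 groups of 20
    ants, each group tested in two treatment cells; planted group-size slope
    0.5 and carbohydrate-by-availability interaction -2.0; group/individual/
    residual SDs 1 / 0.5 / 1) and refits the model with the matching
    group + individual random-intercept structure.
    """
    cfg = cfg or EffectConfig()
    rng = np.random.default_rng(seed)
    ests, covers, contrasts = [], [], []
    for rep in range(n_replicates):
        d = simulate_measures(replace(cfg, seed=int(rng.integers(0, 2**31 - 1))))
        m = MixedModel(spec=RECOVERY_SPEC, criterion="REML").fit(d)
        ests.append(m.coef_)
        ci = m.conf_int(0.95)
        truth = {name: getattr(cfg, attr) for name, attr in TRUE_BETAS.items()}
        truth["Intercept"] = cfg.beta0
        covers.append({name: ci.loc[name, "lower"] <= truth[name] <= ci.loc[name, "upper"]
                       for name in m.coef_.index})
        con = emm_contrasts(m, within="food_type", compare="food_availability")
        carb = con[con["food_type"] == "carbohydrate"]["estimate"].iloc[0]
        contrasts.append(float(carb))
    est_df = pd.DataFrame(ests)
    cover_df = pd.DataFrame(covers)
    truth = {name: getattr(cfg, attr) for name, attr in TRUE_BETAS.items()}
    truth["Intercept"] = cfg.beta0
    return LmmRecoveryStudy(
        n_replicates=n_replicates,
        mean_estimates=est_df.mean().to_dict(),
        true_values=truth,
        coverage=cover_df.mean().to_dict(),
        mean_carb_contrast=float(np.mean(contrasts)),
        contrast_se_mc=float(np.std(contrasts) / np.sqrt(len(contrasts))),
    )


@dataclass
class AicSelectionStudy:
    truth: str
    n_replicates: int
    n_correct: int

    @property
    def rate(self) -> float:
        return self.n_correct / self.n_replicates


def aic_selection_study(truth: str = "type_availability", n_replicates: int = 200,
                        seed: int = 0, cfg: EffectConfig | None = None,
                        ) -> AicSelectionStudy:
    """How often AIC selects the generating fixed-effect structure.

    ``truth="none"`` uses strong main effects and no interaction;
    ``truth="type_availability"`` plants the -2.0 interaction.
    """
    base = cfg or EffectConfig()
    if truth == "none":
        base = replace(base, beta_interaction=0.0, beta_food_type=1.0,
                       beta_availability=1.0)
    elif truth != "type_availability":
        raise ValueError("truth must be 'none' or 'type_availability'")
    rng = np.random.default_rng(seed)
    specs = candidate_specs("degree_like",
                            random_effects=("group_id", "individual_id"))
    correct = 0
    for rep in range(n_replicates):
        d = simulate_measures(replace(base, seed=int(rng.integers(0, 2**31 - 1))))
        best, _ = select_model_aic(specs, d)
        if best.interaction == truth:
            correct += 1
    return AicSelectionStudy(truth=truth, n_replicates=n_replicates, n_correct=correct)


@dataclass
class WaldNullStudy:
    n_fits: int
    ks_statistic: float
    ks_pvalue: float


def wald_null_study(n_fits: int = 1000, seed: int = 0) -> WaldNullStudy:
    """Null calibration of the type II Wald statistic against chi-square(1).

    The generator plants *no* food-type effect; each replicate refits the
    main-effects model and records the food_type Wald statistic.  Sizes (50
    groups, 4 trials each, 5-8 ants per group) keep a thousand refits cheap
    while staying away from small-sample inflation.
    """
    cfg = EffectConfig(
        n_groups=50, trials_per_group=4, group_size_range=(5, 8),
        beta_food_type=0.0, beta_availability=0.5, beta_interaction=0.0,
        sigma_group=1.0, sigma_individual=0.0, sigma_resid=1.0,
    )
    spec = ModelSpec(response="degree_like", interaction="none",
                     random_effects=("group_id",))
    rng = np.random.default_rng(seed)
    stats = []
    for rep in range(n_fits):
        d = simulate_measures(replace(cfg, seed=int(rng.integers(0, 2**31 - 1))))
        m = MixedModel(spec=spec, criterion="REML").fit(d)
        stats.append(float(m.anova().loc["food_type", "chisq"]))
    ks = st.kstest(stats, st.chi2(1).cdf)
    return WaldNullStudy(n_fits=n_fits, ks_statistic=float(ks.statistic),
                         ks_pvalue=float(ks.pvalue))


@dataclass
class GlmmRecoveryStudy:
    n_replicates: int
    true_slope: float
    mean_slope: float


def glmm_recovery_study(n_replicates: int = 20, seed: int = 0) -> GlmmRecoveryStudy:
    """Gamma log-link GLMM slope recovery on log-scale effects."""
    cfg = EffectConfig(
        n_groups=30, trials_per_group=1, group_size_range=(14, 30),
        beta0=1.0, beta_group_size=0.05, beta_food_type=0.1,
        beta_availability=0.1, beta_interaction=0.0,
        sigma_group=0.3, sigma_individual=0.0, sigma_resid=0.0,
    )
    spec = ModelSpec(response="betweenness_like", interaction="none",
                     random_effects=("group_id",), family="gamma")
    rng = np.random.default_rng(seed)
    slopes = []
    for rep in range(n_replicates):
        d = simulate_measures(replace(cfg, seed=int(rng.integers(0, 2**31 - 1))))
        m = MixedModel(spec=spec).fit(d)
        slopes.append(float(m.coef_["group_size"]))
    return GlmmRecoveryStudy(n_replicates=n_replicates, true_slope=0.05,
                             mean_slope=float(np.mean(slopes)))
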