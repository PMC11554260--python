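"""Synthetic colony generators.

Two levels of synthetic input make every downstream stage testable without
the original tracking data:

* trajectory level — :func:`simulate_trial` produces a tag-detection table
  for a group of ants moving in a circular arena (90 mm dish at 0.04 mm/px,
  radius 1125 px) by a correlated random walk, with *planted* head-to-head
  encounters whose pair identities are known exactly (the ground truth for
  interaction-recovery tests);
* measure level — :func:`simulate_measures` produces per-ant response tables
  with a known fixed-effect structure and group / individual / frame-rate
  random intercepts (the oracle for the mixed-model stack).

The movement model is pure test scaffolding, not a behavioural claim: each
ant performs a correlated random walk (wrapped-normal turning angles, gamma
step lengths) confined to a private "home disc".  Home discs are placed by
rejection sampling so that in noiseless mode every *non*-planted pair of ants
stays strictly farther apart than ``separation_factor * threshold_px`` at all
times, while each planted pair walks to a meeting point and holds head-to-head
at less than the threshold for longer than the longest sampling interval, so
at least one sampled frame captures the encounter even at 0.31 images/s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import InfeasibleConfigError
from .tracking import DetectionTable, TrialMetadata, validate_detections

TWO_PI = 2.0 * math.pi

FOOD_TYPES = ("carbohydrate", "protein")
AVAILABILITIES = ("limited", "unlimited")


@dataclass(frozen=True)
class PlantedInteraction:
    """One choreographed head-to-head encounter between two ants."""

    pair: tuple[int, int]        # indices into the trial roster
    onset_s: float
    duration_s: float = 12.0


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of one simulated trial.

    Defaults reproduce the reference study conditions: a 90 mm circular arena
    imaged at 0.04 mm/px (radius 1125 px), 60 min trials, frame rates inside
    [0.31, 2.92] images/s with within-trial variation, and a 102 px
    head-to-head threshold.
    """

    trial_id: str = "T001"
    group_id: str = "G01"
    group_size: int = 20
    arena_radius_px: float = 1125.0
    duration_s: float = 3600.0
    n_rate_segments: int = 3
    frame_rate_range: tuple[float, float] = (0.31, 2.92)
    frame_rates: tuple[float, ...] | None = None  # explicit per-segment rates
    step_scale_px: float = 8.0       # mean step length per second of wander
    turn_sd_rad: float = 0.6         # wrapped-normal turning-angle spread
    wander_radius_px: float = 40.0   # home-disc radius
    n_planted_pairs: int | None = 3  # drawn pairs; ignored if interactions given
    planted_interactions: tuple[PlantedInteraction, ...] | None = None
    threshold_px: float = 102.0
    head_offset_px: float = 0.0
    meet_separation_px: float = 70.0
    travel_time_s: float = 30.0
    interaction_duration_s: float = 12.0
    separation_factor: float = 1.5   # non-planted pairs stay beyond factor*threshold
    food_type: str = "carbohydrate"
    food_availability: str = "unlimited"
    pixel_scale_mm: float = 0.04
    detection_prob: float = 1.0      # < 1 drops detections at random (noisy mode)
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted interaction pairs plus recovery margins and true path lengths."""

    interacting_pairs: set[tuple[str, str]]
    non_interacting_margin_px: float      # min distance ever attained by any other pair
    planted_min_distance_px: float        # max over planted pairs of their min distance
    path_length_px: dict[str, float]      # fine-grid path length per ant

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "interacting_pairs": sorted(list(p) for p in self.interacting_pairs),
            "non_interacting_margin_px": self.non_interacting_margin_px,
            "planted_min_distance_px": self.planted_min_distance_px,
            "path_length_px": self.path_length_px,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def _ant_labels(n: int) -> list[str]:
    return [f"a{i:02d}" for i in range(n)]


def _segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Distance from point p to segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def _segment_segment_distance(a1, b1, a2, b2) -> float:
    """Distance between segments a1b1 and a2b2 (2-D)."""
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    d1, d2 = orient(a2, b2, a1), orient(a2, b2, b1)
    d3, d4 = orient(a1, b1, a2), orient(a1, b1, b2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return 0.0  # proper intersection
    return min(
        _segment_distance(a1, a2, b2), _segment_distance(b1, a2, b2),
        _segment_distance(a2, a1, b1), _segment_distance(b2, a1, b1),
    )


def _place_homes(cfg: TrialConfig, pairs: list[tuple[int, int]], rng: np.random.Generator,
                 ) -> np.ndarray:
    """Place home-disc centers so that separation guarantees hold.

    Planted pairs get two homes ``pair_sep`` apart whose connecting corridor
    (the pair's private capsule) keeps a clearance from every other home and
    corridor; the clearance is chosen so that two wandering ants can never
    come closer than ``separation_factor * threshold_px``.
    """
    margin = cfg.separation_factor * cfg.threshold_px
    pad = 10.0
    clearance = margin + 2.0 * cfg.wander_radius_px + pad
    pair_sep = max(2.0 * cfg.meet_separation_px + 2.0 * cfg.wander_radius_px, 320.0)
    r_eff = cfg.arena_radius_px - cfg.wander_radius_px - pad
    if r_eff <= pair_sep / 2:
        raise InfeasibleConfigError("arena too small for the requested geometry")

    paired = {i for p in pairs for i in p}
    homes = np.full((cfg.group_size, 2), np.nan)
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    points: list[np.ndarray] = []

    def ok_point(p: np.ndarray) -> bool:
        if np.linalg.norm(p) > r_eff:
            return False
        if any(np.linalg.norm(p - q) < clearance for q in points):
            return False
        return all(_segment_distance(p, a, b) >= clearance for a, b in segments)

    def ok_segment(a: np.ndarray, b: np.ndarray) -> bool:
        if np.linalg.norm(a) > r_eff or np.linalg.norm(b) > r_eff:
            return False
        if any(_segment_distance(q, a, b) < clearance for q in points):
            return False
        return all(
            _segment_segment_distance(a, b, a2, b2) >= clearance for a2, b2 in segments
        )

    max_tries = 20000
    for (i, j) in pairs:
        for attempt in range(max_tries):
            center = rng.uniform(-r_eff, r_eff, size=2)
            if np.linalg.norm(center) > r_eff - pair_sep / 2:
                continue
            ang = rng.uniform(0, TWO_PI)
            u = np.array([math.cos(ang), math.sin(ang)])
            a, b = center + u * pair_sep / 2, center - u * pair_sep / 2
            if ok_segment(a, b):
                homes[i], homes[j] = a, b
                segments.append((a, b))
                break
        else:
            raise InfeasibleConfigError(
                f"cannot place planted pair ({i},{j}) with clearance {clearance:.0f} px"
            )
    for i in range(cfg.group_size):
        if i in paired:
            continue
        for attempt in range(max_tries):
            p = rng.uniform(-r_eff, r_eff, size=2)
            if ok_point(p):
                homes[i] = p
                points.append(p)
                break
        else:
            raise InfeasibleConfigError(
                f"cannot place ant {i} with clearance {clearance:.0f} px "
                f"(group too dense for noiseless separation)"
            )
    return homes


def _draw_schedule(cfg: TrialConfig, pairs: list[tuple[int, int]],
                   rng: np.random.Generator) -> list[PlantedInteraction]:
    lo = cfg.travel_time_s + 1.0
    hi = cfg.duration_s - cfg.interaction_duration_s - cfg.travel_time_s - 1.0
    if hi <= lo:
        raise InfeasibleConfigError("trial too short for the interaction choreography")
    return [
        PlantedInteraction(pair=p, onset_s=float(rng.uniform(lo, hi)),
                           duration_s=cfg.interaction_duration_s)
        for p in pairs
    ]


def _sample_times(cfg: TrialConfig, rng: np.random.Generator) -> np.ndarray:
    """Frame timestamps under a piecewise-constant frame-rate schedule."""
    n_seg = max(1, cfg.n_rate_segments)
    if cfg.frame_rates is not None:
        rates = np.asarray(cfg.frame_rates, float)
    else:
        rates = rng.uniform(*cfg.frame_rate_range, size=n_seg)
    edges = np.linspace(0.0, cfg.duration_s, len(rates) + 1)
    times = []
    t = 0.0
    for k, r in enumerate(rates):
        step = 1.0 / float(r)
        while t < edges[k + 1] - 1e-9:
            times.append(t)
            t += step
    if cfg.duration_s - times[-1] > 1e-9:
        times.append(cfg.duration_s)  # close the trial so no step goes unsampled
    return np.asarray(times)


def simulate_trial(config: TrialConfig) -> tuple[DetectionTable, TrialMetadata, GroundTruth]:
    """Simulate one trial; returns detections, metadata and ground truth.

    The same seed yields byte-identical output.  Raises
    :class:`InfeasibleConfigError` when the separation constraints cannot be
    met (too many ants/pairs for the arena) or when a post-hoc brute-force
    distance audit of the sampled frames contradicts the construction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.group_size
    ants = _ant_labels(n)

    # --- planted pairs -----------------------------------------------------
    if cfg.planted_interactions is not None:
        schedule = list(cfg.planted_interactions)
        pairs = [tuple(sorted(s.pair)) for s in schedule]
    else:
        k = 0 if cfg.n_planted_pairs is None else int(cfg.n_planted_pairs)
        if 2 * k > n:
            raise InfeasibleConfigError(f"{k} disjoint pairs need {2*k} ants, have {n}")
        perm = rng.permutation(n)
        pairs = [tuple(sorted((int(perm[2 * i]), int(perm[2 * i + 1])))) for i in range(k)]
        schedule = _draw_schedule(cfg, pairs, rng)
    flat = [i for p in pairs for i in p]
    if len(set(flat)) != len(flat):
        raise InfeasibleConfigError("planted pairs must be disjoint")
    if any(p[0] == p[1] or not (0 <= p[0] < n and 0 <= p[1] < n) for p in pairs):
        raise InfeasibleConfigError("planted pairs must be distinct ants on the roster")

    homes = _place_homes(cfg, pairs, rng)

    # --- fine-grid movement (1 s steps) ------------------------------------
    n_steps = int(round(cfg.duration_s)) + 1
    pos = np.empty((n_steps, n, 2))
    pos[0] = homes + rng.uniform(-1, 1, size=(n, 2)) * (cfg.wander_radius_px * 0.2)
    heading = rng.uniform(0, TWO_PI, size=n)
    theta = np.empty((n_steps, n))
    theta[0] = heading

    # choreography: per ant, list of (t0, t1, p0_resolved_at_runtime, p1, face)
    meet = {}
    for s, p in zip(schedule, pairs):
        i, j = p
        mid = (homes[i] + homes[j]) / 2.0
        ui = homes[i] - mid
        ui /= np.linalg.norm(ui)
        meet[i, s.onset_s] = mid + ui * (cfg.meet_separation_px / 2.0)
        meet[j, s.onset_s] = mid - ui * (cfg.meet_separation_px / 2.0)

    # mode arrays: 0 wander, 1 scripted (linear to target), 2 hold
    script: dict[int, list[tuple[float, float, np.ndarray | None, np.ndarray, int]]] = {
        i: [] for i in range(n)
    }
    for s, p in zip(schedule, pairs):
        for a, b in ((p[0], p[1]), (p[1], p[0])):
            t0, t1 = s.onset_s - cfg.travel_time_s, s.onset_s
            script[a].append((t0, t1, None, meet[a, s.onset_s], 1))               # travel out
            script[a].append((t1, t1 + s.duration_s, None, meet[a, s.onset_s], 2))  # hold
            script[a].append((t1 + s.duration_s, t1 + s.duration_s + cfg.travel_time_s,
                              None, homes[a], 1))                                  # travel home
    for i in range(n):
        script[i].sort(key=lambda r: r[0])

    active: list = [None] * n  # current scripted segment with resolved start point
    partner_of = {}
    for p in pairs:
        partner_of[p[0]], partner_of[p[1]] = p[1], p[0]

    step_shape = 2.0
    for t in range(1, n_steps):
        now = float(t)
        # wander proposal for everyone (keeps the rng stream identical across modes)
        heading = np.mod(heading + rng.normal(0.0, cfg.turn_sd_rad, size=n), TWO_PI)
        steps = rng.gamma(step_shape, cfg.step_scale_px / step_shape, size=n)
        cand = pos[t - 1] + np.column_stack([np.cos(heading), np.sin(heading)]) * steps[:, None]
        # reflect at the home disc
        rel = cand - homes
        d = np.linalg.norm(rel, axis=1)
        out = d > cfg.wander_radius_px
        if out.any():
            dd = d[out]
            scale = np.where(2 * cfg.wander_radius_px - dd > 0,
                             (2 * cfg.wander_radius_px - dd) / dd, 0.0)
            cand[out] = homes[out] + rel[out] * scale[:, None]
        new = cand
        for i in range(n):
            seg = active[i]
            if seg is None:
                for (t0, t1, _p0, target, kind) in script[i]:
                    if t0 <= now - 1.0 < t1:
                        seg = (t0, t1, pos[t - 1, i].copy(), target, kind)
                        active[i] = seg
                        break
            if seg is not None:
                t0, t1, p0, target, kind = seg
                if now >= t1:
                    new[i] = target
                    active[i] = None
                    # fall through to next scripted segment on the next step
                elif kind == 2:
                    new[i] = target
                else:
                    frac = (now - t0) / (t1 - t0)
                    new[i] = p0 + (target - p0) * frac
        moved = new - pos[t - 1]
        pos[t] = new
        nz = np.linalg.norm(moved, axis=1) > 1e-9
        theta[t] = theta[t - 1]
        theta[t, nz] = np.mod(np.arctan2(moved[nz, 1], moved[nz, 0]), TWO_PI)
        # face the partner while holding
        for i in range(n):
            if active[i] is not None and active[i][4] == 2:
                j = partner_of[i]
                v = pos[t, j] - pos[t, i]
                if np.linalg.norm(v) > 0:
                    theta[t, i] = math.atan2(v[1], v[0]) % TWO_PI

    if np.linalg.norm(pos, axis=2).max() > cfg.arena_radius_px + 1e-6:
        raise InfeasibleConfigError("a simulated position left the arena")

    # --- subsample to the frame schedule ------------------------------------
    times = _sample_times(cfg, rng)
    fine_t = np.arange(n_steps, dtype=float)
    idx = np.clip(np.searchsorted(fine_t, times, side="right") - 1, 0, n_steps - 2)
    frac = (times - fine_t[idx])[:, None, None]
    sampled = pos[idx] * (1 - frac) + pos[idx + 1] * frac      # (F, n, 2)
    sampled_theta = theta[np.minimum(idx + (frac[:, 0, 0] > 0.5), n_steps - 1)]

    keep = np.ones((len(times), n), bool)
    if cfg.detection_prob < 1.0:
        keep = rng.uniform(size=keep.shape) < cfg.detection_prob

    rows = {
        "trial_id": [], "frame": [], "time_s": [], "ant_id": [],
        "x_px": [], "y_px": [], "theta_rad": [],
    }
    for f in range(len(times)):
        for i in range(n):
            if not keep[f, i]:
                continue
            rows["trial_id"].append(cfg.trial_id)
            rows["frame"].append(f)
            rows["time_s"].append(round(float(times[f]), 6))
            rows["ant_id"].append(ants[i])
            rows["x_px"].append(round(float(sampled[f, i, 0]), 3))
            rows["y_px"].append(round(float(sampled[f, i, 1]), 3))
            rows["theta_rad"].append(round(float(sampled_theta[f, i]), 6))
    df = pd.DataFrame(rows)
    table = validate_detections(df, trial_id=cfg.trial_id)

    # --- ground truth + audit ------------------------------------------------
    off = cfg.head_offset_px
    heads = sampled + off * np.stack([np.cos(sampled_theta), np.sin(sampled_theta)], axis=-1)
    diff = heads[:, :, None, :] - heads[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)                       # (F, n, n)
    both = keep[:, :, None] & keep[:, None, :]
    dist = np.where(both, dist, np.inf)
    min_d = dist.min(axis=0)
    iu = np.triu_indices(n, k=1)
    planted_mask = np.zeros((n, n), bool)
    for (i, j) in pairs:
        planted_mask[i, j] = planted_mask[j, i] = True
    planted_min = float(min_d[iu][planted_mask[iu]].max()) if pairs else float("nan")
    others = min_d[iu][~planted_mask[iu]]
    margin = float(others.min()) if len(others) else float("inf")
    if pairs and planted_min > cfg.threshold_px:
        raise InfeasibleConfigError(
            f"a planted pair never came within {cfg.threshold_px} px at a sampled frame"
        )
    if cfg.detection_prob >= 1.0 and margin <= cfg.threshold_px:
        raise InfeasibleConfigError(
            f"a non-planted pair came within the threshold (margin {margin:.1f} px)"
        )
    path_len = np.linalg.norm(np.diff(pos, axis=0), axis=2).sum(axis=0)

    truth = GroundTruth(
        interacting_pairs={tuple(sorted((ants[i], ants[j]))) for (i, j) in pairs},
        non_interacting_margin_px=margin,
        planted_min_distance_px=planted_min,
        path_length_px={ants[i]: float(path_len[i]) for i in range(n)},
    )
    fr = (len(times) - 1) / (times[-1] - times[0]) if len(times) > 1 else 1.0
    meta = TrialMetadata(
        trial_id=cfg.trial_id, group_id=cfg.group_id, group_size=n,
        food_type=cfg.food_type, food_availability=cfg.food_availability,
        pixel_scale_mm=cfg.pixel_scale_mm, mean_frame_rate_ips=float(fr),
    )
    return table, meta, truth


@dataclass
class SimulatedTrial:
    table: DetectionTable
    metadata: TrialMetadata
    truth: GroundTruth
    config: TrialConfig


def simulate_experiment(
    n_trials: int = 46,
    seed: int = 0,
    group_size_range: tuple[int, int] = (14, 30),
    n_groups: int | None = None,
    duration_s: float = 600.0,
    planted_pairs_range: tuple[int, int] = (3, 10),
    base_config: TrialConfig | None = None,
) -> list[SimulatedTrial]:
    """Simulate a multi-trial experiment across the four treatment cells.

    Treatments cycle through the 2x2 design; group IDs are reused for a subset
    of trials (as groups were retested in the reference design), which
    exercises the repeated-measures structure downstream.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    base = base_config or TrialConfig()
    n_groups = n_groups or max(1, int(round(0.7 * n_trials)))
    group_of = list(range(n_groups)) + [
        int(rng.integers(0, n_groups)) for _ in range(max(0, n_trials - n_groups))
    ]
    group_of = group_of[:n_trials]
    cells = [(ft, fa) for ft in FOOD_TYPES for fa in AVAILABILITIES]
    sizes = {g: int(rng.integers(group_size_range[0], group_size_range[1] + 1))
             for g in set(group_of)}
    trials = []
    for t in range(n_trials):
        ft, fa = cells[t % 4]
        g = group_of[t]
        size = sizes[g]
        lo, hi = planted_pairs_range
        k = int(rng.integers(lo, min(hi, size // 2) + 1))
        cfg = replace(
            base,
            trial_id=f"T{t + 1:03d}", group_id=f"G{g + 1:02d}", group_size=size,
            duration_s=duration_s, n_planted_pairs=k, food_type=ft,
            food_availability=fa, seed=int(rng.integers(0, 2**31 - 1)),
        )
        table, meta, truth = simulate_trial(cfg)
        trials.append(SimulatedTrial(table, meta, truth, cfg))
    return trials


# --- measure-level generator -------------------------------------------------

@dataclass(frozen=True)
class EffectConfig:
    """Fixed/random-effect structure for the measure-level generator.

    The planted interaction acts in the carbohydrate x unlimited cell: with
    indicator coding I(carbohydrate), I(unlimited), the linear predictor is
    ``beta0 + beta_group_size*size + beta_food_type*I(carb) +
    beta_availability*I(unlim) + beta_interaction*I(carb)*I(unlim)``, so the
    within-carbohydrate availability contrast equals
    ``beta_availability + beta_interaction``.
    """

    n_groups: int = 40
    trials_per_group: int = 2
    group_size_range: tuple[int, int] = (14, 30)
    beta0: float = 10.0
    beta_group_size: float = 0.5
    beta_food_type: float = 0.0       # carbohydrate relative to protein
    beta_availability: float = 0.0    # unlimited relative to limited
    beta_interaction: float = -2.0    # carbohydrate x unlimited cell
    sigma_group: float = 1.0
    sigma_individual: float = 0.5
    sigma_frame_rate: float = 0.0
    sigma_resid: float = 1.0
    gamma_shape: float = 2.0
    frame_rate_range: tuple[float, float] = (0.31, 2.92)
    frame_rate_bin_width: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_group", "sigma_individual", "sigma_frame_rate", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")


def simulate_measures(cfg: EffectConfig) -> pd.DataFrame:
    """Per-ant measure table with known effect structure.

    Columns: treatment metadata plus three responses sharing the same linear
    predictor and random intercepts — ``degree_like`` and ``distance_like``
    (Gaussian residuals) and ``betweenness_like`` (gamma with log link).
    """
    rng = np.random.default_rng(cfg.seed)
    cells = [(ft, fa) for ft in FOOD_TYPES for fa in AVAILABILITIES]
    g_eff = rng.normal(0, cfg.sigma_group, size=cfg.n_groups)
    rows = []
    ind_eff: dict[str, float] = {}
    fr_eff: dict[float, float] = {}
    trial_no = 0
    for g in range(cfg.n_groups):
        size = int(rng.integers(cfg.group_size_range[0], cfg.group_size_range[1] + 1))
        for rep in range(cfg.trials_per_group):
            ft, fa = cells[trial_no % 4]
            trial_no += 1
            rate = float(rng.uniform(*cfg.frame_rate_range))
            rate_bin = round(round(rate / cfg.frame_rate_bin_width) * cfg.frame_rate_bin_width, 6)
            if rate_bin not in fr_eff:
                fr_eff[rate_bin] = rng.normal(0, cfg.sigma_frame_rate)
            is_carb = 1.0 if ft == "carbohydrate" else 0.0
            is_unlim = 1.0 if fa == "unlimited" else 0.0
            eta_fixed = (
                cfg.beta0 + cfg.beta_group_size * size + cfg.beta_food_type * is_carb
                + cfg.beta_availability * is_unlim
                + cfg.beta_interaction * is_carb * is_unlim
            )
            for a in range(size):
                ind = f"G{g + 1:02d}:a{a:02d}"
                if ind not in ind_eff:
                    ind_eff[ind] = rng.normal(0, cfg.sigma_individual)
                eta = eta_fixed + g_eff[g] + ind_eff[ind] + fr_eff[rate_bin]
                rows.append({
                    "trial_id": f"T{trial_no:03d}",
                    "group_id": f"G{g + 1:02d}",
                    "individual_id": ind,
                    "group_size": size,
                    "food_type": ft,
                    "food_availability": fa,
                    "mean_frame_rate_ips": rate,
                    "frame_rate_bin": rate_bin,
                    "eta": eta,
                    "degree_like": eta + rng.normal(0, cfg.sigma_resid),
                    "distance_like": eta + rng.normal(0, cfg.sigma_resid),
                    "betweenness_like": rng.gamma(cfg.gamma_shape,
                                                  math.exp(eta) / cfg.gamma_shape),
                })
    return pd.DataFrame(rows)
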