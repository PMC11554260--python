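import numpy as np
import pandas as pd
import pytest

from trophnet.errors import InfeasibleConfigError
from trophnet.simulate import (
    EffectConfig,
    PlantedInteraction,
    TrialConfig,
    simulate_experiment,
    simulate_measures,
    simulate_trial,
)
from trophnet.studies import brute_force_edges
from trophnet.tracking import build_trajectories


class TestSimulateTrial:
    def test_no_planted_pairs_empty_truth(self):
        _, _, truth = simulate_trial(TrialConfig(group_size=8, duration_s=200.0,
                                                 n_planted_pairs=0, seed=1))
        assert truth.interacting_pairs == set()

    def test_planted_pairs_are_exactly_the_close_pairs(self):
        cfg = TrialConfig(
            group_size=8, duration_s=300.0, seed=2,
            planted_interactions=(
                PlantedInteraction(pair=(1, 2), onset_s=80.0),
                PlantedInteraction(pair=(3, 4), onset_s=180.0),
            ),
        )
        table, _, truth = simulate_trial(cfg)
        assert truth.interacting_pairs == {("a01", "a02"), ("a03", "a04")}
        # independent brute-force recomputation of per-frame pair distances
        traj = build_trajectories(table)
        assert brute_force_edges(traj, cfg.threshold_px) == truth.interacting_pairs

    def test_same_seed_identical_output(self):
        cfg = TrialConfig(group_size=10, duration_s=200.0, seed=7)
        t1, m1, g1 = simulate_trial(cfg)
        t2, m2, g2 = simulate_trial(cfg)
        pd.testing.assert_frame_equal(t1.df, t2.df)
        assert m1 == m2
        assert g1.interacting_pairs == g2.interacting_pairs

    def test_positions_stay_inside_arena(self):
        cfg = TrialConfig(group_size=14, duration_s=300.0, seed=3)
        table, _, _ = simulate_trial(cfg)
        r = np.hypot(table.df["x_px"], table.df["y_px"])
        assert (r <= cfg.arena_radius_px).all()

    def test_margin_exceeds_threshold_for_non_planted(self):
        _, _, truth = simulate_trial(TrialConfig(group_size=12, duration_s=300.0,
                                                 n_planted_pairs=3, seed=5))
        assert truth.non_interacting_margin_px > 1.5 * 102.0 - 1e-9
        assert truth.planted_min_distance_px <= 102.0

    def test_too_many_pairs_infeasible(self):
        with pytest.raises(InfeasibleConfigError):
            simulate_trial(TrialConfig(group_size=6, n_planted_pairs=4, seed=0))

    def test_overcrowded_arena_infeasible(self):
        with pytest.raises(InfeasibleConfigError):
            simulate_trial(TrialConfig(group_size=40, arena_radius_px=300.0,
                                       duration_s=120.0, n_planted_pairs=0, seed=0))

    def test_metadata_carries_treatment(self):
        _, meta, _ = simulate_trial(TrialConfig(group_size=8, duration_s=200.0,
                                                food_type="protein",
                                                food_availability="limited", seed=1))
        assert (meta.food_type, meta.food_availability) == ("protein", "limited")


class TestSimulateExperiment:
    def test_four_trials_cover_treatment_cells(self):
        sims = simulate_experiment(n_trials=4, seed=0, duration_s=150.0)
        cells = {(s.metadata.food_type, s.metadata.food_availability) for s in sims}
        assert len(cells) == 4

    def test_group_sizes_within_range(self):
        sims = simulate_experiment(n_trials=10, seed=1, duration_s=120.0)
        assert all(14 <= s.metadata.group_size <= 30 for s in sims)

    def test_group_reuse_recorded(self):
        sims = simulate_experiment(n_trials=10, n_groups=4, seed=2, duration_s=120.0)
        counts = pd.Series([s.metadata.group_id for s in sims]).value_counts()
        assert counts.max() >= 2  # at least one group retested
        # same group keeps the same size across trials
        sizes = {}
        for s in sims:
            sizes.setdefault(s.metadata.group_id, set()).add(s.metadata.group_size)
        assert all(len(v) == 1 for v in sizes.values())


class TestSimulateMeasures:
    def test_all_effects_zero_constant_response(self):
        cfg = EffectConfig(n_groups=4, beta0=3.0, beta_group_size=0.0,
                           beta_food_type=0.0, beta_availability=0.0,
                           beta_interaction=0.0, sigma_group=0.0,
                           sigma_individual=0.0, sigma_resid=0.0, seed=0)
        d = simulate_measures(cfg)
        assert np.allclose(d["degree_like"], 3.0)

    def test_group_variance_moments(self):
        """sigma_group dominates: between-group variance ~ sigma_group^2."""
        cfg = EffectConfig(n_groups=400, trials_per_group=1,
                           group_size_range=(25, 25),
                           beta_group_size=0.0, beta_food_type=0.0,
                           beta_availability=0.0, beta_interaction=0.0,
                           sigma_group=2.0, sigma_individual=0.0,
                           sigma_resid=0.0, seed=3)
        d = simulate_measures(cfg)
        assert len(d) >= 10_000
        gm = d.groupby("group_id")["degree_like"].agg(["mean", "var"])
        assert gm["var"].fillna(0).max() == pytest.approx(0.0, abs=1e-12)
        assert gm["mean"].var() == pytest.approx(4.0, rel=0.25)

    def test_gamma_response_positive_and_log_linked(self):
        d = simulate_measures(EffectConfig(n_groups=10, seed=1))
        assert (d["betweenness_like"] > 0).all()

    def test_interaction_acts_in_carbohydrate_unlimited_cell(self):
        cfg = EffectConfig(n_groups=400, trials_per_group=4,
                           group_size_range=(20, 20), beta_group_size=0.0,
                           sigma_group=0.0, sigma_individual=0.0,
                           sigma_resid=0.0, seed=2)
        d = simulate_measures(cfg)
        cell = d.groupby(["food_type", "food_availability"])["degree_like"].mean()
        carb_contrast = (cell["carbohydrate", "unlimited"] - cell["carbohydrate", "limited"])
        prot_contrast = (cell["protein", "unlimited"] - cell["protein", "limited"])
        assert carb_contrast == pytest.approx(
            cfg.beta_availability + cfg.beta_interaction, abs=1e-9)
        assert prot_contrast == pytest.approx(cfg.beta_availability, abs=1e-9)

    def test_seeded_determinism(self):
        cfg = EffectConfig(n_groups=6, seed=9)
        pd.testing.assert_frame_equal(simulate_measures(cfg), simulate_measures(cfg))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            EffectConfig(sigma_group=-1.0)
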