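import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from trophnet.design import ModelSpec, build_design, candidate_specs
from trophnet.errors import MissingFactorError, RankDeficientDesignError
from trophnet.inference import (
    MixedModel,
    emm_contrasts,
    fit_lmm,
    r2_components,
    select_model_aic,
    wald_type2_anova,
)
from trophnet.simulate import EffectConfig, simulate_measures


@pytest.fixture(scope="module")
def measures():
    return simulate_measures(EffectConfig(n_groups=24, seed=5))


def spec_for(interaction="none", response="degree_like",
             random_effects=("group_id", "individual_id")):
    return ModelSpec(response=response, interaction=interaction,
                     random_effects=random_effects)


class TestDesign:
    def test_five_candidates_plus_polynomial(self):
        specs = candidate_specs("y", include_polynomial=True)
        assert len(specs) == 6
        assert {s.interaction for s in specs[:5]} == {
            "none", "type_availability", "size_type", "size_availability", "three_way"}
        assert specs[5].poly_group_size

    def test_three_way_has_full_factorial_columns(self, measures):
        d = build_design(spec_for("three_way"), measures)
        assert len(d.column_names) == 8
        assert len([t for t in d.terms if t.name != "Intercept"]) == 7

    def test_interaction_implies_main_effects_ordering(self, measures):
        d = build_design(spec_for("type_availability"), measures)
        t = d.term("food_type:food_availability")
        assert {r.name for r in d.relatives(d.term("food_type"))} == {
            "food_type:food_availability"}
        assert d.relatives(t) == []

    def test_single_level_factor_rank_deficient(self, measures):
        sub = measures[measures["food_type"] == "protein"]
        with pytest.raises(RankDeficientDesignError):
            build_design(spec_for("none"), sub)

    def test_reference_levels_flip_sign(self, measures):
        m1 = MixedModel(spec=spec_for("type_availability")).fit(measures)
        m2 = MixedModel(spec=spec_for("type_availability"),
                        reference_levels={"food_type": "carbohydrate"}).fit(measures)
        a = m1.coef_["food_type[carbohydrate]"]
        b = m2.coef_["food_type[protein]"]
        # different parameterisation, same cell means: contrast at limited cell
        assert a == pytest.approx(-b, rel=1e-6)


class TestWaldType2:
    def test_single_binary_term_equals_z_squared(self, measures):
        m = MixedModel(spec=spec_for("none")).fit(measures)
        tab = m.anova()
        z2 = (m.coef_["food_availability[unlimited]"]
              / m.se_["food_availability[unlimited]"]) ** 2
        assert tab.loc["food_availability", "chisq"] == pytest.approx(z2, rel=1e-9)
        assert tab.loc["food_availability", "df"] == 1

    def test_three_way_table_structure(self, measures):
        m = MixedModel(spec=spec_for("three_way")).fit(measures)
        tab = m.anova()
        assert len(tab) == 7
        assert (tab["df"] == 1).all()
        assert (tab["chisq"] >= 0).all()

    def test_main_effect_marginal_to_interaction(self, measures):
        """Type II: the main-effect test ignores its higher-order relative,
        so adding an interaction does not change which hypothesis is tested
        (estimates shift slightly because the variance model refits)."""
        m0 = MixedModel(spec=spec_for("none"), criterion="ML").fit(measures)
        m1 = MixedModel(spec=spec_for("type_availability"), criterion="ML").fit(measures)
        t0 = m0.anova().loc["group_size", "chisq"]
        t1 = m1.anova().loc["group_size", "chisq"]
        assert t1 == pytest.approx(t0, rel=0.05)

    def test_polynomial_term_two_df(self, measures):
        m = MixedModel(spec=ModelSpec(response="degree_like", poly_group_size=True,
                                      random_effects=("group_id",))).fit(measures)
        assert m.anova().loc["poly(group_size,2)", "df"] == 2


class TestR2:
    def test_zero_random_variance_zero_share(self, rng):
        cfg = EffectConfig(n_groups=30, sigma_group=0.0, sigma_individual=0.0,
                           sigma_resid=1.0, seed=2)
        m = MixedModel(spec=spec_for("type_availability",
                                     random_effects=("group_id",))).fit(
            simulate_measures(cfg))
        _, _, share = r2_components(m)
        assert share == pytest.approx(0.0, abs=2.0)

    def test_equal_group_and_residual_variance_fifty_percent(self):
        cfg = EffectConfig(n_groups=120, trials_per_group=2,
                           beta_group_size=0.0, beta_food_type=0.0,
                           beta_availability=0.0, beta_interaction=0.0,
                           sigma_group=1.0, sigma_individual=0.0,
                           sigma_resid=1.0, seed=3)
        m = MixedModel(spec=spec_for("none", random_effects=("group_id",))).fit(
            simulate_measures(cfg))
        r2m, r2c, share = r2_components(m)
        assert r2m == pytest.approx(0.0, abs=0.02)
        assert share == pytest.approx(50.0, abs=6.0)

    def test_ordering_invariant(self, measures):
        m = MixedModel(spec=spec_for("type_availability")).fit(measures)
        r2m, r2c, share = r2_components(m)
        assert 0.0 <= r2m <= r2c <= 1.0
        assert share == pytest.approx(100 * (r2c - r2m))


class TestEmmContrasts:
    def test_balanced_design_equals_cell_mean_difference(self, rng):
        # balanced 2x2 with identical group-size distribution per cell
        rows = []
        gid = 0
        for ft in ("carbohydrate", "protein"):
            for fa in ("limited", "unlimited"):
                for gs in (15, 20, 25, 30):
                    gid += 1
                    for a in range(6):
                        rows.append({
                            "group_id": f"G{gid}", "individual_id": f"G{gid}:a{a}",
                            "group_size": gs, "food_type": ft,
                            "food_availability": fa,
                            "y": (2.0 * (ft == "carbohydrate")
                                  + 1.0 * (fa == "unlimited")
                                  - 3.0 * (ft == "carbohydrate") * (fa == "unlimited")
                                  + 0.1 * gs + float(rng.normal(0, 0.3))),
                        })
        d = pd.DataFrame(rows)
        spec = ModelSpec(response="y", interaction="type_availability",
                         random_effects=("group_id",))
        m = MixedModel(spec=spec).fit(d)
        con = emm_contrasts(m)
        cells = d.groupby(["food_type", "food_availability"])["y"].mean()
        for ft in ("carbohydrate", "protein"):
            est = con[con["food_type"] == ft]["estimate"].iloc[0]
            raw = cells[ft, "unlimited"] - cells[ft, "limited"]
            assert est == pytest.approx(raw, abs=0.02)

    def test_two_level_tukey_equals_t_test(self, measures):
        m = MixedModel(spec=spec_for("type_availability")).fit(measures)
        con = emm_contrasts(m)
        for _, row in con.iterrows():
            p_t = 2 * st.t.sf(abs(row["t_ratio"]), row["df"])
            assert row["p_value"] == pytest.approx(p_t, rel=1e-9)
            # studentized-range check: q = t*sqrt(2) with k=2 gives the same p
            p_q = st.studentized_range.sf(abs(row["t_ratio"]) * np.sqrt(2),
                                          2, row["df"])
            assert row["p_value"] == pytest.approx(p_q, rel=1e-3)

    def test_satterthwaite_df_finite_positive(self, measures):
        m = MixedModel(spec=spec_for("type_availability")).fit(measures)
        con = emm_contrasts(m)
        assert ((con["df"] > 1) & (con["df"] < 1e7)).all()

    def test_unknown_factor_rejected(self, measures):
        m = MixedModel(spec=spec_for("type_availability")).fit(measures)
        with pytest.raises(MissingFactorError):
            emm_contrasts(m, within="group_size")
        with pytest.raises(MissingFactorError):
            emm_contrasts(m, within="food_type", compare="food_type")


class TestSelection:
    def test_tie_broken_stably_toward_first(self, measures):
        spec = spec_for("none")
        best, table = select_model_aic([spec, spec], measures)
        assert best == spec
        assert table["aic"].iloc[0] == table["aic"].iloc[1]

    def test_table_sorted_and_delta(self, measures):
        best, table = select_model_aic(
            candidate_specs("degree_like",
                            random_effects=("group_id", "individual_id")), measures)
        assert table["aic"].is_monotonic_increasing
        assert table["delta_aic"].iloc[0] == 0.0
        assert best.interaction == "type_availability"  # the planted structure

    def test_refit_under_reml_after_ml_selection(self, measures):
        best, _ = select_model_aic(
            candidate_specs("degree_like",
                            random_effects=("group_id", "individual_id")), measures)
        reml = fit_lmm(best, measures, criterion="REML")
        ml = fit_lmm(best, measures, criterion="ML")
        assert reml.loglik_ != ml.loglik_
        assert reml.coef_["group_size"] == pytest.approx(
            ml.coef_["group_size"], rel=0.02)
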