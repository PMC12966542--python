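"""Mixed-model moderation fits: exact-fit limits, OLS equivalence,
Wald-table invariants and the person-level PTA regressions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from audema import (ModelSpec, add_decomposition, fit_between_regression,
                    fit_moderation_model, score_table, simulate_study)
from audema.models import coefficient_table, fit_mixed_model

from conftest import noise_free_config, small_config


def _scored(study):
    scored, _ = score_table(study.ema)
    scored = scored.merge(study.participants, on="participant_id")
    return add_decomposition(scored)


class TestModerationModel:
    def test_noise_free_recovers_generating_slopes(self):
        cfg = noise_free_config(seed=21, residual_sd=1e-6,
                                random_intercept_sd=0.5,
                                a_soc=0.0, a_subj=0.0,
                                a_mod_pta=0.0, a_mod_env=0.35)
        scored = _scored(simulate_study(cfg))
        res = fit_moderation_model(scored, ModelSpec("effort",
                                                     "environmental"))
        # within-person terms are exact in this limit (person-level terms
        # keep the random-intercept draw as irreducible error)
        assert res.beta("environmental_demand_wp") == pytest.approx(
            cfg.a_env, abs=1e-4)
        assert res.beta("environmental_demand_wp:pta_z") == pytest.approx(
            cfg.a_mod_env, abs=1e-4)

    def test_single_prompt_zero_variance_matches_ols(self):
        # one prompt per participant and no random-intercept variance:
        # the mixed model collapses to ordinary least squares on the
        # person-level design
        from audema.models import prepare_model_frame
        cfg = small_config(seed=12, n_days=1, prompts_per_day=1,
                           window_anchors=(9.0,), final_day_prompts=1,
                           compliance_by_day=(1.0,))
        for o in (cfg.effort, cfg.affect, cfg.fatigue):
            o.random_intercept_sd = 0.0
        scored = _scored(simulate_study(cfg))
        df, _ = prepare_model_frame(
            scored, ModelSpec("effort", "subjective"))
        formula = ("effort ~ subjective_demand_bp + pta_z + sleep_quality"
                   " + sleep_hours + age + sex")
        mixed = fit_mixed_model(df, formula)
        ols = smf.ols(formula, df).fit()
        for term in ("subjective_demand_bp", "pta_z", "sleep_quality"):
            assert mixed.beta(term) == pytest.approx(ols.params[term],
                                                     abs=1e-4)

    def test_fit_invariant_to_participant_relabeling(self, scored_frame):
        scored, _ = scored_frame
        relabeled = scored.copy()
        mapping = {pid: f"Q{i}" for i, pid in
                   enumerate(sorted(scored["participant_id"].unique())[::-1])}
        relabeled["participant_id"] = relabeled["participant_id"].map(mapping)
        a = fit_moderation_model(scored, ModelSpec("fatigue", "social"))
        b = fit_moderation_model(relabeled, ModelSpec("fatigue", "social"))
        assert np.allclose(a.coefficients["beta"], b.coefficients["beta"],
                           atol=1e-8)

    def test_wald_ci_width_identity(self, scored_frame):
        scored, _ = scored_frame
        res = fit_moderation_model(scored, ModelSpec("effort", "social"))
        width = res.coefficients["ci_upper"] - res.coefficients["ci_lower"]
        assert np.allclose(width, 2 * 1.96 * res.coefficients["se"],
                           atol=1e-8)

    def test_non_centered_within_column_rejected(self, scored_frame):
        scored, _ = scored_frame
        broken = scored.copy()
        broken["environmental_demand_wp"] = (
            broken["environmental_demand_wp"] + 0.5)
        with pytest.raises(ValueError, match="person-mean center"):
            fit_moderation_model(broken, ModelSpec("effort", "environmental"))

    def test_rank_deficient_design_names_terms(self, scored_frame):
        scored, _ = scored_frame
        dup = scored.copy()
        dup["sleep_hours"] = dup["sleep_quality"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            fit_moderation_model(dup, ModelSpec("effort", "environmental"))

    def test_coefficient_table_significance_flags(self):
        tab = coefficient_table(pd.Series({"a": 1.0, "b": 0.01}),
                                pd.Series({"a": 0.1, "b": 0.1}))
        assert bool(tab.loc["a", "significant"])
        assert not bool(tab.loc["b", "significant"])


class TestBetweenRegression:
    def test_perfect_linear_relation(self):
        participants = pd.DataFrame({
            "participant_id": list("ABCDE"),
            "pta": [0.0, 10.0, 20.0, 30.0, 40.0]})
        scored = pd.DataFrame({
            "participant_id": list("ABCDE"),
            "answered": True,
            "subjective_demand": 0.009 * participants["pta"] + 0.5})
        reg = fit_between_regression(participants, scored, "subjective")
        assert reg.slope == pytest.approx(0.009, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0)

    def test_null_relation_large_sample(self, rng):
        n = 400
        participants = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "pta": rng.normal(30, 15, n)})
        scored = pd.DataFrame({
            "participant_id": participants["participant_id"],
            "answered": True,
            "subjective_demand": rng.normal(1.0, 0.3, n)})
        reg = fit_between_regression(participants, scored, "subjective")
        assert abs(reg.slope) < 3 * reg.se

    def test_r_squared_equals_squared_pearson(self, rng):
        n = 60
        participants = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "pta": rng.normal(30, 15, n)})
        demand = (0.01 * participants["pta"] + rng.normal(0, 0.3, n))
        scored = pd.DataFrame({
            "participant_id": participants["participant_id"],
            "answered": True, "subjective_demand": demand})
        reg = fit_between_regression(participants, scored, "subjective")
        r = np.corrcoef(participants["pta"], demand)[0, 1]
        assert reg.r_squared == pytest.approx(r ** 2, abs=1e-12)

    def test_zero_pta_variance_rejected(self):
        participants = pd.DataFrame({
            "participant_id": list("ABC"), "pta": [20.0, 20.0, 20.0]})
        scored = pd.DataFrame({"participant_id": list("ABC"),
                               "answered": True,
                               "subjective_demand": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="zero variance"):
            fit_between_regression(participants, scored, "subjective")


def _frame_for_ols(scored):
    from audema.models import prepare_model_frame
    return prepare_model_frame(scored, ModelSpec("effort", "subjective"))
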