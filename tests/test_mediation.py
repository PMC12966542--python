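"""Mediation paths, Monte-Carlo indirect CIs and pattern labels."""

import numpy as np
import pytest

from audema import (MediationConfig, add_decomposition, classify_pattern,
                    monte_carlo_indirect, run_mediation, score_table,
                    simulate_study)
from audema.mediation import conditional_indirect

from conftest import noise_free_config


def _scored(study):
    scored, _ = score_table(study.ema)
    scored = scored.merge(study.participants, on="participant_id")
    return add_decomposition(scored)


@pytest.fixture(scope="module")
def noise_free_mediation():
    """Noise-free chain with known path algebra: a=0.8, b=0.2,
    direct=-0.06 so that c = a*b + direct = 0.10."""
    cfg = noise_free_config(seed=31, a_env=0.8, a_soc=0.0, a_subj=0.0,
                            a_mod_pta=0.0, a_mod_env=0.15,
                            affect_a_subj=0.0,
                            b_effort=0.2, b_affect=0.0,
                            direct_env=-0.06, direct_soc=0.0,
                            direct_subj=0.0)
    # scale separation: tiny mediator noise identifies the b-path, far
    # tinier outcome noise keeps every estimate at its generating value
    cfg.effort.residual_sd = 1e-5
    cfg.affect.residual_sd = 1e-5
    cfg.fatigue.residual_sd = 1e-10
    scored = _scored(simulate_study(cfg))
    return run_mediation(scored, "environmental", "effort",
                         MediationConfig(seed=1)), cfg


class TestMonteCarloIndirect:
    def test_printed_coefficients_round_to_reported_indirect(self):
        point, ci = monte_carlo_indirect(0.77, 0.02, 0.23, 0.02, seed=1)
        assert round(point, 2) == 0.18
        assert ci[0] < point < ci[1]

    def test_degenerate_se_collapses_ci(self):
        point, ci = monte_carlo_indirect(0.5, 0.0, 0.4, 0.0, seed=1)
        assert ci == (point, point) == (0.2, 0.2)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_indirect(0.5, -0.1, 0.4, 0.02)

    def test_ci_width_shrinks_as_root_draws(self):
        # the endpoint standard error scales ~ draws^(-1/2): estimate the
        # spread of the upper endpoint over repeats at 4k vs 64k draws
        ups_4k, ups_64k = [], []
        for s in range(40):
            _, ci = monte_carlo_indirect(0.5, 0.1, 0.3, 0.1, 4000, seed=s)
            ups_4k.append(ci[1])
            _, ci = monte_carlo_indirect(0.5, 0.1, 0.3, 0.1, 64000,
                                         seed=1000 + s)
            ups_64k.append(ci[1])
        ratio = np.std(ups_4k) / np.std(ups_64k)
        assert ratio == pytest.approx(4.0, rel=0.5)

    def test_matches_analytic_product_distribution(self):
        # numerical quantiles of the product of two independent normals
        # via Gauss-Hermite conditioning: P(XY<=t) = E_X[Phi((t/x-b)/sb)]
        from scipy import stats
        a, sa, b, sb = 0.4, 0.15, 0.3, 0.1
        point, ci = monte_carlo_indirect(a, sa, b, sb, draws=10 ** 6, seed=3)

        nodes, weights = np.polynomial.hermite_e.hermegauss(201)
        x = a + sa * nodes
        w = weights / weights.sum()

        def cdf(t):
            arg = (t / x - b) / sb
            return float(np.sum(w * np.where(x > 0, stats.norm.cdf(arg),
                                             stats.norm.sf(arg))))

        from scipy.optimize import brentq
        lo = brentq(lambda t: cdf(t) - 0.025, -1, 1)
        hi = brentq(lambda t: cdf(t) - 0.975, -1, 1)
        assert ci[0] == pytest.approx(lo, abs=0.005)
        assert ci[1] == pytest.approx(hi, abs=0.005)


class TestClassification:
    def test_reported_patterns(self):
        # direct effect flips sign and stays significant -> suppression
        assert classify_pattern(0.07, 0.001, -0.10, 1e-4,
                                (0.15, 0.20)) == "suppression"
        # direct effect becomes nonsignificant -> full/attenuated
        assert classify_pattern(0.38, 1e-4, 0.02, 0.67,
                                (0.29, 0.42)) == "full/attenuated"
        # interval covering zero -> no mediation
        assert classify_pattern(0.3, 1e-4, 0.25, 1e-4,
                                (-0.02, 0.03)) == "no mediation"
        # significant same-sign direct effect -> partial
        assert classify_pattern(0.4, 1e-4, 0.2, 1e-4,
                                (0.1, 0.3)) == "partial"


class TestMediationPipeline:
    def test_noise_free_path_algebra(self, noise_free_mediation):
        res, cfg = noise_free_mediation
        assert res.a == pytest.approx(0.8, abs=1e-6)
        assert res.b == pytest.approx(0.2, abs=1e-6)
        assert res.c_prime == pytest.approx(-0.06, abs=1e-6)
        assert res.c == pytest.approx(res.c_prime + res.a * res.b, abs=1e-6)
        assert res.indirect == res.a * res.b
        assert res.a_moderation == pytest.approx(0.15, abs=1e-6)

    def test_models_share_analysis_rows(self, noise_free_mediation):
        res, _ = noise_free_mediation
        assert (res.model_a.n_obs == res.model_b.n_obs == res.model_c.n_obs
                == res.n_obs)

    def test_conditional_indirect_linear_in_moderator(self,
                                                      noise_free_mediation):
        res, _ = noise_free_mediation
        tab = conditional_indirect(res, (-1.0, 0.0, 1.0))
        vals = tab["indirect"].to_numpy()
        assert vals[1] == pytest.approx(res.indirect)
        assert vals[2] - vals[1] == pytest.approx(
            res.a_moderation * res.b, abs=1e-9)

    def test_deterministic_given_seed(self, scored_frame):
        scored, _ = scored_frame
        a = run_mediation(scored, "social", "effort",
                          MediationConfig(seed=11))
        b = run_mediation(scored, "social", "effort",
                          MediationConfig(seed=11))
        assert a.indirect == b.indirect
        assert a.indirect_ci == b.indirect_ci
        assert a.pattern == b.pattern

    def test_identity_mediator_limit(self):
        # when fatigue IS the mediator (b=1, no direct path), Model B
        # recovers b = 1 and c' = 0 in the noise-free limit
        cfg = noise_free_config(seed=41, a_env=0.8, a_soc=0.0, a_subj=0.0,
                                a_mod_pta=0.0, affect_a_subj=0.0,
                                b_effort=1.0, b_affect=0.0, direct_env=0.0,
                                direct_soc=0.0, direct_subj=0.0)
        cfg.effort.residual_sd = 1e-5
        cfg.fatigue.residual_sd = 1e-10
        cfg.fatigue.intercept = 0.0
        cfg.fatigue.time_of_day = 0.0
        scored = _scored(simulate_study(cfg))
        res = run_mediation(scored, "environmental", "effort",
                            MediationConfig(seed=2, interaction=False))
        assert res.b == pytest.approx(1.0, abs=1e-6)
        assert res.c_prime == pytest.approx(0.0, abs=1e-6)

    def test_shuffled_demand_gives_null_a_path(self, scored_frame, rng):
        scored, _ = scored_frame
        shuffled = scored.copy()
        answered = shuffled["answered"].astype(bool)
        grp = shuffled.loc[answered].groupby("participant_id")
        col = "environmental_demand_wp"
        shuffled.loc[answered, col] = grp[col].transform(
            lambda s: rng.permutation(s.to_numpy()))
        res = run_mediation(shuffled, "environmental", "effort",
                            MediationConfig(seed=5))
        assert abs(res.a) < 3 * res.se_a
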