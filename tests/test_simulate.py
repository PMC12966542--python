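"""Synthetic-study generator: distributions, schedule, compliance,
determinism and the noise-free truth-model identity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from audema import (TruthConfig, apply_compliance, compute_pta,
                    generate_participants, generate_schedule, score_table,
                    simulate_study)
from audema.config import ConfigurationError
from audema.simulate import simulate_responses

from conftest import noise_free_config, small_config


class TestComputePta:
    def test_better_ear_mean(self):
        assert compute_pta((10, 10, 20, 20), (20, 30, 40, 50)) == 15.0

    def test_perfect_hearing(self):
        assert compute_pta((0, 0, 0, 0), (0, 0, 0, 0)) == 0.0

    def test_random_audiograms_match_min_of_means(self, rng):
        for _ in range(50):
            left = rng.uniform(-10, 110, 4)
            right = rng.uniform(-10, 110, 4)
            expected = min(sum(left) / 4, sum(right) / 4)
            assert compute_pta(left, right) == pytest.approx(expected)

    def test_missing_frequency_named_in_error(self):
        with pytest.raises(ValueError, match="2000 Hz"):
            compute_pta({500: 10, 1000: 10, 4000: 20},
                        {500: 0, 1000: 0, 2000: 0, 4000: 0})


class TestParticipants:
    def test_pta_moments_match_target(self):
        cfg = TruthConfig(n_participants=10000, seed=3)
        p = generate_participants(cfg)
        se = cfg.pta_sd / np.sqrt(len(p))
        assert abs(p["pta"].mean() - 27.4) < 3 * se
        assert p["pta"].std(ddof=1) == pytest.approx(20.1, rel=0.05)
        assert p["pta"].between(-5, 93.75).all()

    def test_zero_sd_degenerates_to_point_mass(self):
        p = generate_participants(small_config(pta_sd=0))
        assert (p["pta"] == 27.4).all()

    def test_same_seed_gives_identical_roster(self):
        a = generate_participants(small_config(seed=9))
        b = generate_participants(small_config(seed=9))
        assert a.to_csv() == b.to_csv()

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(pta_sd=-1.0)


class TestSchedule:
    def test_zero_jitter_hits_window_midpoints(self):
        cfg = small_config(jitter_halfwidth_min=0)
        p = generate_participants(cfg)
        sched = generate_schedule(cfg, p, rng=1)
        assert np.allclose(sched["prompt_time"],
                           sched["window_anchor"] + 0.25)

    def test_jitter_bounded_and_uniform(self):
        cfg = TruthConfig(n_participants=2700, seed=2)  # ~10^5 prompts
        p = generate_participants(cfg)
        sched = generate_schedule(cfg, p, rng=2)
        offsets = (sched["prompt_time"] - sched["window_anchor"] - 0.25) * 60
        assert len(offsets) > 1e5
        assert offsets.min() >= -15 and offsets.max() <= 15
        ks = stats.kstest(offsets, stats.uniform(loc=-15, scale=30).cdf)
        assert ks.pvalue > 0.01

    def test_half_day_truncation_count(self):
        cfg = TruthConfig(n_participants=2, seed=1)
        p = generate_participants(cfg)
        sched = generate_schedule(cfg, p, rng=1)
        per_person = sched.groupby("participant_id").size()
        assert (per_person == 5 * 7 + 3).all()
        last_day = sched[sched["day"] == 6]
        assert sorted(last_day["window_anchor"].unique()) == [9.0, 11.0, 13.5]

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            small_config(window_anchors=(9.0, 9.2, 13.5, 15.0, 17.0, 19.0,
                                         21.0))


class TestCompliance:
    def test_full_compliance_no_missingness(self):
        cfg = small_config(compliance_by_day=(1.0, 1.0, 1.0))
        study = simulate_study(cfg)
        assert study.ema["answered"].all()

    def test_zero_compliance_fails_downstream_cleanly(self):
        cfg = small_config(compliance_by_day=(0.0, 0.0, 0.0))
        study = simulate_study(cfg)
        assert not study.ema["answered"].any()
        with pytest.raises(ValueError, match="no analyzable data|no answered"):
            score_table(study.ema)

    def test_rate_out_of_bounds_rejected(self, small_study):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            apply_compliance(small_study.ema, [1.2, 0.5, 0.5], rng=0)

    def test_unanswered_rows_keep_design_but_not_outcomes(self, small_study):
        missing = small_study.ema[~small_study.ema["answered"]]
        assert len(missing) > 0
        assert missing["effort"].isna().all()
        assert missing["who_with"].isna().all()
        assert missing["day"].notna().all()

    def test_missingness_independent_of_fatigue(self):
        # MCAR by construction: logistic slope of answered on the
        # generated fatigue value is null (|z| < 3 at ~10^4 prompts)
        import statsmodels.api as sm
        cfg = TruthConfig(n_participants=280, seed=17, keep_latent=True)
        p = generate_participants(cfg, rng=np.random.default_rng(17))
        rng = np.random.default_rng(18)
        sched = generate_schedule(cfg, p, rng)
        resp, _ = simulate_responses(p, sched, cfg, rng)
        fatigue = resp["fatigue"].to_numpy()
        masked = apply_compliance(resp, cfg.compliance_by_day, rng)
        X = sm.add_constant(fatigue)
        fit = sm.Logit(masked["answered"].astype(float), X).fit(disp=0)
        assert abs(np.asarray(fit.tvalues)[1]) < 3


class TestResponses:
    def test_scale_closure(self, small_study):
        a = small_study.ema[small_study.ema["answered"]]
        assert a["difficulty"].between(1, 5).all()
        assert a["importance"].between(1, 5).all()
        for col in ("effort", "fatigue", "feeling_now"):
            assert a[col].between(0, 10).all()
        for col in [f"pos{i}" for i in range(1, 5)] + [f"neg{i}" for i in
                                                       range(1, 6)]:
            assert a[col].between(1, 7).all()
        latency = a["timestamp_hours"] - a["window_anchor"]
        assert (latency >= 0).all()
        assert (latency <= 0.5 + 40 / 60).all()

    def test_noise_free_outcomes_equal_linear_predictor(self):
        study = simulate_study(noise_free_config())
        a = study.ema[study.ema["answered"]]
        assert np.allclose(a["effort"], a["effort_lin"])
        assert np.allclose(a["feeling_now"], a["affect_lin"])
        assert np.allclose(a["fatigue"], a["fatigue_lin"])

    def test_determinism_byte_identical(self):
        a = simulate_study(small_config(seed=33))
        b = simulate_study(small_config(seed=33))
        assert a.ema.to_csv() == b.ema.to_csv()
        assert a.participants.to_csv() == b.participants.to_csv()

    def test_subjective_demand_rises_with_pta(self):
        # the configured hearing-loss link should make the person-level
        # demand/PTA correlation clearly positive
        cfg = TruthConfig(n_participants=300, seed=8)
        study = simulate_study(cfg)
        scored, _ = score_table(study.ema)
        pm = (scored[scored["answered"]]
              .groupby("participant_id")["subjective_demand"].mean())
        df = study.participants.set_index("participant_id").join(pm)
        r = df["pta"].corr(df["subjective_demand"])
        assert r > 0.3

    def test_alone_is_modal_who_with_state(self, small_study):
        a = small_study.ema[small_study.ema["answered"]]
        modal = a["who_with"].value_counts().idxmax()
        assert modal == "Alone"

    def test_excess_clipping_emits_warning(self, caplog):
        cfg = small_config()
        cfg.effort.intercept = 25.0  # push far beyond the slider ceiling
        import logging
        with caplog.at_level(logging.WARNING, logger="audema.simulate"):
            simulate_study(cfg)
        assert any("clipped" in rec.message for rec in caplog.records)
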