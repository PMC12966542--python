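"""Named study conditions used across the analyses and validation runs.

Three generator configurations are frozen here so that every consumer
(analysis drivers, tests, the acceptance script) simulates the same
conditions:

* :func:`default_study` — the full emulated protocol: 130 participants,
  5.5 days x 7 daytime prompts, declining day-specific compliance, the
  observed hearing-loss distribution, and causal slopes matching the
  reported within-person effect sizes.  Outcome means sit near the
  observed study means, which puts real mass at the slider floors and
  ceilings (the clipping the generator logs).
* :func:`parameter_recovery_study` — the design used for slope-recovery
  validation: 200 participants x 35 prompts (5 full days), full
  compliance, moderate noise, outcome means mid-scale and floor/ceiling
  censoring disabled, so the estimators are evaluated under the linear
  model they assume (even ~0.5% censored prompts visibly attenuate the
  demand x hearing-loss interaction, which lives in the extreme cells).
  Generating values: demand->effort a-path 0.77, a-path x PTA moderation
  0.34, effort->fatigue b-path 0.23, time-of-day fatigue slope 0.13.
* :func:`null_mediation_study` — a small design with every demand->
  mediator path and its moderation set to zero, for false-positive
  calibration of the Monte-Carlo indirect-effect interval.
"""

from __future__ import annotations

from .config import OutcomeParams, TruthConfig

RECOVERY_TRUTH = {
    "a_env": 0.77,
    "a_mod_pta": 0.34,
    "b_effort": 0.23,
    "fatigue_time_of_day": 0.13,
}


def default_study(seed: int = 20260925) -> TruthConfig:
    """The emulated 130-participant, 5.5-day protocol (package defaults)."""
    return TruthConfig(seed=seed)


def parameter_recovery_study(seed: int) -> TruthConfig:
    """Clip-light 200 x 35 design for estimator validation.

    Covariate slopes are kept small and time-of-day enters fatigue only,
    so the fitted total fatigue model's time coefficient equals the
    generating 0.13 exactly.
    """
    return TruthConfig(
        seed=seed,
        n_participants=200,
        n_days=5,
        final_day_prompts=7,
        compliance_by_day=(1.0,) * 5,
        clip_outcomes=False,
        a_env=RECOVERY_TRUTH["a_env"],
        a_soc=0.40,
        a_subj=0.80,
        a_mod_pta=RECOVERY_TRUTH["a_mod_pta"],
        affect_a_subj=-0.10,
        b_effort=RECOVERY_TRUTH["b_effort"],
        b_affect=-0.20,
        direct_env=-0.10,
        direct_soc=-0.06,
        direct_subj=0.02,
        a_subj_between=0.6,
        effort=OutcomeParams(
            intercept=3.5, pta_main=0.2, time_of_day=0.0,
            sleep_quality=-0.10, sleep_hours=0.0, age=0.0, sex_male=-0.1,
            random_intercept_sd=0.8, residual_sd=1.0),
        affect=OutcomeParams(
            intercept=3.7, pta_main=-0.1, time_of_day=0.0,
            sleep_quality=0.30, sleep_hours=0.0, age=0.0, sex_male=0.0,
            random_intercept_sd=0.8, residual_sd=1.0),
        fatigue=OutcomeParams(
            intercept=3.2, pta_main=0.1,
            time_of_day=RECOVERY_TRUTH["fatigue_time_of_day"],
            sleep_quality=-0.10, sleep_hours=0.0, age=0.0, sex_male=-0.1,
            random_intercept_sd=0.9, residual_sd=1.1),
    )


def null_mediation_study(seed: int, n_participants: int = 40,
                         prompts_per_day: int = 5, n_days: int = 2,
                         ) -> TruthConfig:
    """Small design with a zero a-path everywhere (mediation null)."""
    cfg = parameter_recovery_study(seed)
    anchors = (9.0, 11.0, 13.5, 15.0, 17.0, 19.0, 21.0)[:prompts_per_day]
    return TruthConfig(
        seed=seed,
        n_participants=n_participants,
        n_days=n_days,
        prompts_per_day=prompts_per_day,
        window_anchors=anchors,
        final_day_prompts=prompts_per_day,
        compliance_by_day=(1.0,) * n_days,
        clip_outcomes=False,
        a_env=0.0, a_soc=0.0, a_subj=0.0, a_mod_pta=0.0,
        a_env_between=0.0, a_soc_between=0.0, a_subj_between=0.0,
        affect_a_env=0.0, affect_a_soc=0.0, affect_a_subj=0.0,
        b_effort=0.23, b_affect=-0.20,
        direct_env=0.0, direct_soc=0.0, direct_subj=0.0,
        effort=cfg.effort, affect=cfg.affect, fatigue=cfg.fatigue,
    )
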