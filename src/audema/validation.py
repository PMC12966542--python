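"""Simulation-based validation runs: slope recovery and mediation
false-positive calibration.

These helpers run one replicate each of the named study conditions in
:mod:`audema.study_designs` through the full analysis path (simulate ->
score -> decompose -> mixed models / mediation) and return the estimates
a validation study aggregates over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .decompose import add_decomposition
from .mediation import MediationConfig, run_mediation
from .scoring import score_table
from .simulate import simulate_study
from .study_designs import null_mediation_study, parameter_recovery_study


def scored_study(config) -> pd.DataFrame:
    """Simulate one study and return its scored + decomposed table."""
    study = simulate_study(config)
    scored, _ = score_table(study.ema)
    scored = scored.merge(study.participants, on="participant_id")
    return add_decomposition(scored)


@dataclass
class RecoveryEstimates:
    """Point estimates and SEs from one recovery replicate."""

    a: float
    se_a: float
    a_mod: float
    se_a_mod: float
    b: float
    se_b: float
    time_of_day: float
    se_time_of_day: float
    n_obs: int

    def covers(self, truth: dict[str, float]) -> dict[str, bool]:
        """Whether each 95% Wald CI covers its generating value."""
        return {
            "a": abs(self.a - truth["a_env"]) <= 1.96 * self.se_a,
            "a_mod": abs(self.a_mod - truth["a_mod_pta"])
                     <= 1.96 * self.se_a_mod,
            "b": abs(self.b - truth["b_effort"]) <= 1.96 * self.se_b,
            "time_of_day": abs(self.time_of_day
                               - truth["fatigue_time_of_day"])
                           <= 1.96 * self.se_time_of_day,
        }


def recovery_replicate(seed: int) -> RecoveryEstimates:
    """One slope-recovery replicate at the 200 x 35 validation design.

    The environmental-demand mediation triplet supplies every quantity:
    Model A is the effort moderation model (a-path and its PTA
    interaction), Model B the b-path, and Model C the total fatigue model
    whose time-of-day coefficient is checked as a covariate-recovery
    control.
    """
    scored = scored_study(parameter_recovery_study(seed))
    med = run_mediation(scored, "environmental", "effort",
                        MediationConfig(seed=seed))
    mc = med.model_c
    return RecoveryEstimates(
        a=med.a, se_a=med.se_a,
        a_mod=med.a_moderation, se_a_mod=med.se_a_moderation,
        b=med.b, se_b=med.se_b,
        time_of_day=mc.beta("time_of_day"),
        se_time_of_day=mc.se("time_of_day"),
        n_obs=med.n_obs)


def null_indirect_replicate(seed: int) -> tuple[float, tuple[float, float]]:
    """Indirect estimate and Monte-Carlo CI under a zero a-path truth."""
    scored = scored_study(null_mediation_study(seed))
    med = run_mediation(scored, "environmental", "effort",
                        MediationConfig(seed=seed))
    return med.indirect, med.indirect_ci
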