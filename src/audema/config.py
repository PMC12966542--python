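"""Study configuration: sampling design, covariate distributions and the
multilevel truth model used by the synthetic-study generator.

The defaults describe a 130-participant, 5.5-day ecological momentary
assessment (EMA) study with 7 daytime prompts per day, day-specific
compliance declining from 83% to 67%, and a hearing-loss (PTA) distribution
centred at 27.4 dB HL (SD 20.1).  The causal defaults encode a
within-person demand -> listening-effort -> fatigue chain whose a-path is
amplified by hearing loss, which is the structure the downstream models
are built to estimate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a TruthConfig violates one of its invariants."""


# Clock-hour starts of the seven daytime 30-min prompt windows.
DEFAULT_WINDOW_ANCHORS = (9.0, 11.0, 13.5, 15.0, 17.0, 19.0, 21.0)

DEFAULT_COMPLIANCE = (0.83, 0.79, 0.75, 0.75, 0.70, 0.67)


@dataclass
class OutcomeParams:
    """Linear-predictor coefficients for one momentary outcome.

    Slopes are in outcome units per predictor unit; `pta_main` is per SD of
    PTA (the moderator enters z-scored), and the sd fields are the
    person-level random-intercept and momentary residual standard
    deviations.
    """

    intercept: float = 0.0
    pta_main: float = 0.0
    time_of_day: float = 0.0
    sleep_quality: float = 0.0
    sleep_hours: float = 0.0
    age: float = 0.0
    sex_male: float = 0.0
    random_intercept_sd: float = 1.0
    residual_sd: float = 1.0


@dataclass
class TruthConfig:
    # --- sampling design ---
    n_participants: int = 130
    n_days: int = 6
    prompts_per_day: int = 7
    window_anchors: tuple[float, ...] = DEFAULT_WINDOW_ANCHORS
    # day n_days is truncated: only the first `final_day_prompts` windows
    # fire, realising the 5.5-day protocol (morning through ~13:30).
    final_day_prompts: int = 3
    jitter_halfwidth_min: float = 15.0
    max_latency_min: float = 40.0
    compliance_by_day: tuple[float, ...] = DEFAULT_COMPLIANCE

    # --- person-level covariate distributions ---
    pta_mean: float = 27.4
    pta_sd: float = 20.1
    pta_lo: float = -5.0
    pta_hi: float = 93.75
    age_mean: float = 58.3
    age_sd: float = 8.6
    prop_male: float = 0.30
    sleep_quality_mean: float = 4.9
    sleep_quality_sd: float = 0.9
    sleep_hours_mean: float = 7.3
    sleep_hours_sd: float = 0.8

    # --- momentary context / item generation ---
    # categorical mixes over the printed answer options (normalised on use)
    who_with_probs: dict[str, float] = field(default_factory=lambda: {
        "Alone": 0.45,
        "Partner": 0.20,
        "Children": 0.06,
        "One or more colleagues": 0.09,
        "Family (besides your partner and children)": 0.04,
        "Friend(s)": 0.10,
        "Other": 0.06,
    })
    situation_probs: dict[str, float] = field(default_factory=lambda: {
        "Conversation with 1 person": 0.18,
        "Conversation with more than 1 person": 0.17,
        "Phone conversation": 0.05,
        "Actively listening to a speaker (live)": 0.05,
        "Actively listening to TV, radio, etc.": 0.22,
        "Ambient noise": 0.13,
        "Passive listening, not an active listening task": 0.20,
    })
    multi_select_prob: float = 0.15   # chance a prompt reports a 2nd option
    context_person_sd: float = 0.40   # person tilt (log-weight) on context mixes

    # Difficulty/importance: 1 + Binomial(4, p) with a person-specific p.
    difficulty_p0: float = 0.275
    importance_p0: float = 0.38
    difficulty_person_sd: float = 0.14
    importance_person_sd: float = 0.08
    # dB^-1 shift of the difficulty propensity: links hearing loss to
    # subjective demand (calibrated so the between-person slope of mean
    # subjective demand rank on raw PTA is ~0.009 per dB HL).
    pta_difficulty_slope: float = 0.0045

    # --- causal truth model ---
    # demand -> effort within-person slopes (a-paths)
    a_env: float = 0.77
    a_soc: float = 0.96
    a_subj: float = 1.81
    # demand(within) x PTA(z) slope on effort (a-path moderation); applied
    # to each demand's within-person deviation, with optional per-demand
    # overrides
    a_mod_pta: float = 0.35
    a_mod_env: float | None = None
    a_mod_soc: float | None = None
    a_mod_subj: float | None = None
    # between-person demand -> effort slopes (default: same as within)
    a_env_between: float | None = None
    a_soc_between: float | None = None
    a_subj_between: float | None = None
    # demand -> affect
    affect_a_env: float = 0.0
    affect_a_soc: float = 0.0
    affect_a_subj: float = -0.10
    # mediator -> fatigue slopes
    b_effort: float = 0.22
    b_affect: float = -0.30
    # residual direct demand -> fatigue paths (c-prime analogues)
    direct_env: float = -0.10
    direct_soc: float = -0.06
    direct_subj: float = 0.02

    effort: OutcomeParams = field(default_factory=lambda: OutcomeParams(
        intercept=0.75, pta_main=1.2, time_of_day=0.03, sleep_quality=-0.40,
        sleep_hours=0.14, age=-0.02, sex_male=-0.30,
        random_intercept_sd=1.0, residual_sd=1.5))
    affect: OutcomeParams = field(default_factory=lambda: OutcomeParams(
        intercept=2.6, pta_main=-0.10, time_of_day=0.01, sleep_quality=0.78,
        sleep_hours=-0.06, age=0.03, sex_male=0.0,
        random_intercept_sd=1.1, residual_sd=1.3))
    fatigue: OutcomeParams = field(default_factory=lambda: OutcomeParams(
        intercept=8.75, pta_main=0.3, time_of_day=0.12, sleep_quality=-0.60,
        sleep_hours=0.12, age=-0.04, sex_male=-0.70,
        random_intercept_sd=1.2, residual_sd=1.5))

    # keep pre-clipping linear predictors as extra columns (debugging /
    # noise-free identity checks)
    keep_latent: bool = False
    # clip outcomes to the 0-10 slider bounds (turn off to study the
    # estimators free of floor/ceiling censoring)
    clip_outcomes: bool = True

    seed: int = 20260925

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.pta_sd < 0:
            raise ConfigurationError("pta_sd must be >= 0")
        if self.prompts_per_day != len(self.window_anchors):
            raise ConfigurationError(
                "prompts_per_day must equal the number of window anchors")
        if not 0 <= self.final_day_prompts <= self.prompts_per_day:
            raise ConfigurationError("final_day_prompts out of range")
        if len(self.compliance_by_day) != self.n_days:
            raise ConfigurationError(
                f"compliance_by_day needs {self.n_days} entries, "
                f"got {len(self.compliance_by_day)}")
        for p in self.compliance_by_day:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"compliance probability {p} not in [0,1]")
        for name in ("effort", "affect", "fatigue"):
            out = getattr(self, name)
            if out.random_intercept_sd < 0 or out.residual_sd < 0:
                raise ConfigurationError(f"{name}: sds must be >= 0")
        anchors = list(self.window_anchors)
        if anchors != sorted(anchors):
            raise ConfigurationError("window anchors must be increasing")
        # 30-min windows must not overlap
        for lo, hi in zip(anchors, anchors[1:]):
            if hi - lo < 0.5:
                raise ConfigurationError(
                    f"prompt windows starting at {lo} and {hi} overlap")

    # --- derived design quantities ---
    def prompts_for_day(self, day: int) -> int:
        """Number of prompt windows fired on 1-based study day `day`."""
        if day == self.n_days:
            return self.final_day_prompts
        return self.prompts_per_day

    @property
    def total_prompts_per_participant(self) -> int:
        return sum(self.prompts_for_day(d) for d in range(1, self.n_days + 1))

    # --- YAML round trip ---
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "TruthConfig":
        data = dict(data)
        for name in ("effort", "affect", "fatigue"):
            if name in data and isinstance(data[name], dict):
                data[name] = OutcomeParams(**data[name])
        for name in ("window_anchors", "compliance_by_day"):
            if name in data and isinstance(data[name], list):
                data[name] = tuple(data[name])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
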