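"""Synthetic EMA study generator.

Generates complete simulated studies — participant roster with audiometric
and lifestyle covariates, a jittered daytime prompt schedule, momentary
item responses driven by a multilevel causal truth model, and day-specific
missingness — so every downstream analysis stage can be exercised and
validated without access to real data.

The truth model is a linear chain per prompt:

    demand (environmental, social, subjective)
        -> listening effort   (a-paths; a-path amplified by PTA z-score)
        -> fatigue            (b-path), plus residual direct demand paths
    subjective demand -> affect -> fatigue

with person random intercepts and momentary Gaussian noise on each
outcome.  Outcomes are generated on the latent scale and then clipped to
their 0-10 slider bounds; the clipping rate is logged and a warning is
emitted when it exceeds 5% (a bias hazard for slope recovery).

Missingness is missing-completely-at-random: each prompt is answered with
its study day's compliance probability, independent of all generated
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, TruthConfig
from .scoring import (SITUATION_SCORES, WHO_WITH_SCORES, MULTI_SELECT_SEP,
                      TertileCutpoints, fit_tertiles)

logger = logging.getLogger(__name__)

PTA_FREQUENCIES = (500, 1000, 2000, 4000)

RESPONSE_COLUMNS = [
    "timestamp_hours", "difficulty", "importance", "who_with", "situation",
    "pos1", "pos2", "pos3", "pos4", "neg1", "neg2", "neg3", "neg4", "neg5",
    "feeling_now", "effort", "fatigue",
]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def compute_pta(left_thresholds, right_thresholds) -> float:
    """Pure-tone average: better-ear mean threshold at 500/1000/2000/4000 Hz.

    Accepts per-ear threshold mappings keyed by frequency (Hz) or length-4
    sequences ordered (500, 1000, 2000, 4000).
    """

    def _ear(thresholds, side: str) -> float:
        if isinstance(thresholds, dict):
            missing = [f for f in PTA_FREQUENCIES if f not in thresholds]
            if missing:
                raise ValueError(
                    f"{side} ear: missing threshold at {missing[0]} Hz")
            vals = [float(thresholds[f]) for f in PTA_FREQUENCIES]
        else:
            vals = [float(v) for v in thresholds]
            if len(vals) != 4:
                raise ValueError(
                    f"{side} ear: need 4 thresholds "
                    f"(500/1000/2000/4000 Hz), got {len(vals)}")
        return sum(vals) / 4.0

    return min(_ear(left_thresholds, "left"), _ear(right_thresholds, "right"))


def _truncnorm_params(mean: float, sd: float, lo: float, hi: float,
                      ) -> tuple[float, float]:
    """Parent-normal (loc, scale) whose [lo, hi]-truncation has the
    requested mean and sd, so the generated sample matches the target
    moments rather than the pre-truncation ones."""
    from scipy.optimize import fsolve

    def moments(params):
        loc, scale = params
        scale = abs(scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale,
                                     moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    (loc, scale), info, ok, msg = fsolve(moments, [mean, sd],
                                         full_output=True)
    if ok != 1:
        raise ConfigurationError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} "
            f"on [{lo}, {hi}]: {msg}")
    return float(loc), float(abs(scale))


def generate_participants(config: TruthConfig,
                          rng: np.random.Generator | int | None = None,
                          ) -> pd.DataFrame:
    """Draw a participant roster with PTA and person-level covariates.

    PTA is truncated-normal on the configured mean/sd, bounded to the
    plausible observed range; age, sleep quality and sleep hours are
    clipped normals; sex is Bernoulli (0 = female, 1 = male); hearing-aid
    use becomes more likely with worse hearing.
    """
    config.validate()
    if config.pta_sd < 0:
        raise ConfigurationError("pta_sd must be >= 0")
    rng = _as_rng(rng if rng is not None else config.seed)
    n = config.n_participants

    if config.pta_sd == 0:
        pta = np.full(n, config.pta_mean)
    else:
        loc, scale = _truncnorm_params(config.pta_mean, config.pta_sd,
                                       config.pta_lo, config.pta_hi)
        a = (config.pta_lo - loc) / scale
        b = (config.pta_hi - loc) / scale
        pta = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n,
                                  random_state=rng)

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 95.0)
    sex = (rng.random(n) < config.prop_male).astype(int)
    sleep_quality = np.clip(
        rng.normal(config.sleep_quality_mean, config.sleep_quality_sd, n),
        1.0, 7.0)
    sleep_hours = np.clip(
        rng.normal(config.sleep_hours_mean, config.sleep_hours_sd, n),
        3.0, 12.0)
    hearing_aid = (rng.random(n) < 1.0 / (1.0 + np.exp(-(pta - 25.0) / 8.0))
                   ).astype(int)

    return pd.DataFrame({
        "participant_id": [f"P{i + 1:03d}" for i in range(n)],
        "pta": pta,
        "age": age,
        "sex": sex,
        "sleep_quality": sleep_quality,
        "sleep_hours": sleep_hours,
        "hearing_aid": hearing_aid,
    })


def generate_schedule(config: TruthConfig,
                      participants: pd.DataFrame,
                      rng: np.random.Generator | int | None = None,
                      ) -> pd.DataFrame:
    """Jittered daytime prompt times for every participant-day.

    Each prompt fires at its 30-min window's midpoint plus a uniform
    jitter of up to +/- `jitter_halfwidth_min` minutes.  The final study
    day is truncated to the first `final_day_prompts` windows, realising
    the half day.
    """
    config.validate()
    rng = _as_rng(rng)
    anchors = np.asarray(config.window_anchors)
    jit = config.jitter_halfwidth_min / 60.0

    rows = []
    for pid in participants["participant_id"]:
        for day in range(1, config.n_days + 1):
            k = config.prompts_for_day(day)
            for j in range(k):
                rows.append((pid, day, j + 1, anchors[j]))
    sched = pd.DataFrame(rows, columns=["participant_id", "day", "prompt",
                                        "window_anchor"])
    midpoint = sched["window_anchor"].to_numpy() + 0.25
    jitter = rng.uniform(-jit, jit, len(sched))
    sched["prompt_time"] = midpoint + jitter
    return sched


def _tilted_weights(base: dict[str, float], scores: dict[str, int],
                    tilt: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Per-person categorical weights, exponentially tilted along the
    demand axis: w_ik proportional to base_k * exp(tilt_i * score_k)."""
    labels = list(base)
    b = np.asarray([base[k] for k in labels], dtype=float)
    s = np.asarray([scores[k] for k in labels], dtype=float)
    w = b[None, :] * np.exp(tilt[:, None] * s[None, :])
    return labels, w / w.sum(axis=1, keepdims=True)


def _sample_categorical(weights_rows: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Vectorised categorical draw: one index per row of weights."""
    cum = np.cumsum(weights_rows, axis=1)
    u = rng.random(len(weights_rows)) * cum[:, -1]
    return (u[:, None] < cum).argmax(axis=1)


def _sample_selections(person_weights: np.ndarray, person_idx: np.ndarray,
                       labels: list[str], multi_prob: float,
                       rng: np.random.Generator,
                       ) -> tuple[list[str], np.ndarray]:
    """Draw a (possibly two-option) multi-select answer per prompt.

    Returns semicolon-joined label strings and the max base score per row.
    """
    w = person_weights[person_idx]
    first = _sample_categorical(w, rng)
    add_second = rng.random(len(first)) < multi_prob
    w2 = w.copy()
    w2[np.arange(len(first)), first] = 0.0
    second = _sample_categorical(w2, rng)
    score_of = np.asarray([
        SITUATION_SCORES.get(lab, WHO_WITH_SCORES.get(lab)) for lab in labels
    ], dtype=float)

    strings = []
    for i, f in enumerate(first):
        if add_second[i]:
            strings.append(labels[f] + MULTI_SELECT_SEP + labels[second[i]])
        else:
            strings.append(labels[f])
    scores = score_of[first].copy()
    scores[add_second] = np.maximum(scores[add_second],
                                    score_of[second[add_second]])
    return strings, scores


def _person_deviation(values: np.ndarray, person_idx: np.ndarray,
                      n_persons: int) -> tuple[np.ndarray, np.ndarray]:
    """(deviation-from-person-mean per row, person mean per person)."""
    sums = np.bincount(person_idx, weights=values, minlength=n_persons)
    counts = np.bincount(person_idx, minlength=n_persons)
    means = sums / counts
    return values - means[person_idx], means


@dataclass
class SimulatedStudy:
    """A complete simulated study plus generation bookkeeping."""

    participants: pd.DataFrame
    ema: pd.DataFrame
    config: TruthConfig
    generator_cutpoints: TertileCutpoints | None = None
    clip_rates: dict[str, float] = field(default_factory=dict)


def _bound(values: np.ndarray, config: TruthConfig) -> np.ndarray:
    return np.clip(values, 0, 10) if config.clip_outcomes else values


def simulate_responses(participants: pd.DataFrame, schedule: pd.DataFrame,
                       config: TruthConfig,
                       rng: np.random.Generator | int | None = None,
                       ) -> tuple[pd.DataFrame, dict]:
    """Generate item responses for every scheduled prompt.

    Contexts are drawn from person-tilted categorical mixes; difficulty
    and importance are shifted-binomial ordinals with the difficulty
    propensity increasing with PTA; effort, affect and fatigue follow the
    configured linear truth model and are clipped to 0-10.

    Returns the response table (one row per prompt, all answered) and an
    info dict with clip rates and the generator's tertile cutpoints.
    """
    config.validate()
    rng = _as_rng(rng)
    n = len(participants)
    pid_to_idx = {pid: i for i, pid in
                  enumerate(participants["participant_id"])}
    person_idx = schedule["participant_id"].map(pid_to_idx).to_numpy()
    m = len(schedule)

    pta = participants["pta"].to_numpy()
    if np.std(pta, ddof=1 if n > 1 else 0) > 0:
        pta_z = (pta - pta.mean()) / pta.std(ddof=1)
    else:
        pta_z = np.zeros(n)

    # ---- person-level latent draws ----
    tilt_env = rng.normal(0.0, config.context_person_sd, n)
    tilt_soc = rng.normal(0.0, config.context_person_sd, n)
    diff_p = np.clip(
        config.difficulty_p0
        + config.pta_difficulty_slope * (pta - config.pta_mean)
        + rng.normal(0.0, config.difficulty_person_sd, n),
        0.02, 0.98)
    imp_p = np.clip(
        config.importance_p0 + rng.normal(0.0, config.importance_person_sd, n),
        0.02, 0.98)
    u_eff = rng.normal(0.0, config.effort.random_intercept_sd, n)
    u_aff = rng.normal(0.0, config.affect.random_intercept_sd, n)
    u_fat = rng.normal(0.0, config.fatigue.random_intercept_sd, n)

    # ---- momentary contexts and ordinal items ----
    sit_labels, sit_w = _tilted_weights(config.situation_probs,
                                        SITUATION_SCORES, tilt_env)
    who_labels, who_w = _tilted_weights(config.who_with_probs,
                                        WHO_WITH_SCORES, tilt_soc)
    situation, env_score = _sample_selections(
        sit_w, person_idx, sit_labels, config.multi_select_prob, rng)
    who_with, soc_score = _sample_selections(
        who_w, person_idx, who_labels, config.multi_select_prob, rng)

    difficulty = 1 + rng.binomial(4, diff_p[person_idx])
    importance = 1 + rng.binomial(4, imp_p[person_idx])
    product = (difficulty * importance).astype(float)
    cuts = fit_tertiles(product)
    subj_score = np.where(product <= cuts.lower, 0.0,
                          np.where(product <= cuts.upper, 1.0, 2.0))

    # response latency: survey answered shortly after the prompt fires
    latency = np.minimum(rng.exponential(2.0, m), config.max_latency_min) / 60.0
    timestamp = schedule["prompt_time"].to_numpy() + latency

    # ---- truth model ----
    dev_env, pm_env = _person_deviation(env_score, person_idx, n)
    dev_soc, pm_soc = _person_deviation(soc_score, person_idx, n)
    dev_subj, pm_subj = _person_deviation(subj_score, person_idx, n)

    P = participants  # person covariates broadcast to rows
    age_r = P["age"].to_numpy()[person_idx]
    sex_r = P["sex"].to_numpy()[person_idx]
    sq_r = P["sleep_quality"].to_numpy()[person_idx]
    sh_r = P["sleep_hours"].to_numpy()[person_idx]
    ptaz_r = pta_z[person_idx]

    def _covs(p) -> np.ndarray:
        return (p.intercept + p.pta_main * ptaz_r + p.time_of_day * timestamp
                + p.sleep_quality * sq_r + p.sleep_hours * sh_r
                + p.age * age_r + p.sex_male * sex_r)

    aB_env = config.a_env if config.a_env_between is None else config.a_env_between
    aB_soc = config.a_soc if config.a_soc_between is None else config.a_soc_between
    aB_subj = config.a_subj if config.a_subj_between is None else config.a_subj_between

    mod_env = config.a_mod_pta if config.a_mod_env is None else config.a_mod_env
    mod_soc = config.a_mod_pta if config.a_mod_soc is None else config.a_mod_soc
    mod_subj = (config.a_mod_pta if config.a_mod_subj is None
                else config.a_mod_subj)
    effort_lin = (_covs(config.effort)
                  + config.a_env * dev_env + config.a_soc * dev_soc
                  + config.a_subj * dev_subj
                  + aB_env * pm_env[person_idx] + aB_soc * pm_soc[person_idx]
                  + aB_subj * pm_subj[person_idx]
                  + ptaz_r * (mod_env * dev_env + mod_soc * dev_soc
                              + mod_subj * dev_subj)
                  + u_eff[person_idx])
    effort = _bound(effort_lin
                    + rng.normal(0.0, config.effort.residual_sd, m), config)

    affect_lin = (_covs(config.affect)
                  + config.affect_a_env * env_score
                  + config.affect_a_soc * soc_score
                  + config.affect_a_subj * subj_score
                  + u_aff[person_idx])
    affect = _bound(affect_lin
                    + rng.normal(0.0, config.affect.residual_sd, m), config)

    # fatigue is driven by the *observed* (clipped) mediators, so the
    # b-paths the analyst estimates are the generating ones
    fatigue_lin = (_covs(config.fatigue)
                   + config.b_effort * effort + config.b_affect * affect
                   + config.direct_env * env_score
                   + config.direct_soc * soc_score
                   + config.direct_subj * subj_score
                   + u_fat[person_idx])
    fatigue = _bound(fatigue_lin
                     + rng.normal(0.0, config.fatigue.residual_sd, m), config)

    # mood sliders correlated with the momentary affect state
    pos = np.clip(4.0 + 0.30 * (affect[:, None] - 5.0)
                  + rng.normal(0.0, 0.7, (m, 4)), 1, 7)
    neg = np.clip(3.2 - 0.28 * (affect[:, None] - 5.0)
                  + rng.normal(0.0, 0.6, (m, 5)), 1, 7)

    ema = schedule.copy()
    ema["timestamp_hours"] = timestamp
    ema["answered"] = True
    ema["difficulty"] = difficulty.astype(float)
    ema["importance"] = importance.astype(float)
    ema["who_with"] = who_with
    ema["situation"] = situation
    for j in range(4):
        ema[f"pos{j + 1}"] = pos[:, j]
    for j in range(5):
        ema[f"neg{j + 1}"] = neg[:, j]
    ema["feeling_now"] = affect
    ema["effort"] = effort
    ema["fatigue"] = fatigue
    if config.keep_latent:
        ema["effort_lin"] = effort_lin
        ema["affect_lin"] = affect_lin
        ema["fatigue_lin"] = fatigue_lin

    clip_rates = {}
    for name, lin, obs, sd_cfg in (
            ("effort", effort_lin, effort, config.effort),
            ("affect", affect_lin, affect, config.affect),
            ("fatigue", fatigue_lin, fatigue, config.fatigue)):
        rate = float(np.mean((obs == 0.0) | (obs == 10.0)))
        clip_rates[name] = rate
        if rate > 0.05:
            logger.warning(
                "%s: %.1f%% of generated values were clipped to the 0-10 "
                "scale; slope recovery may be biased", name, 100 * rate)

    info = {"clip_rates": clip_rates, "generator_cutpoints": cuts}
    return ema, info


def apply_compliance(responses: pd.DataFrame, compliance_by_day,
                     rng: np.random.Generator | int | None = None,
                     ) -> pd.DataFrame:
    """Mark each prompt answered with its day's probability (MCAR).

    Unanswered prompts are retained as rows with ``answered == False``
    and all response fields set to missing; the missingness draw is
    independent of every generated value by construction.
    """
    rates = list(compliance_by_day)
    for p in rates:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"compliance probability {p} not in [0,1]")
    rng = _as_rng(rng)
    out = responses.copy()
    day = out["day"].to_numpy()
    if day.max() > len(rates):
        raise ValueError(
            f"no compliance rate for day {int(day.max())}")
    p_row = np.asarray(rates)[day - 1]
    answered = rng.random(len(out)) < p_row
    out["answered"] = answered
    missing = ~answered
    for col in RESPONSE_COLUMNS:
        if col in ("who_with", "situation"):
            out.loc[missing, col] = np.nan
        else:
            out.loc[missing, col] = np.nan
    return out


def simulate_study(config: TruthConfig,
                   rng: np.random.Generator | int | None = None,
                   ) -> SimulatedStudy:
    """Run the full generator: roster -> schedule -> responses -> compliance.

    A single seeded random stream drives every stage, so an identical
    config (including seed) reproduces the study byte for byte.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    participants = generate_participants(config, rng)
    schedule = generate_schedule(config, participants, rng)
    responses, info = simulate_responses(participants, schedule, config, rng)
    ema = apply_compliance(responses, config.compliance_by_day, rng)
    return SimulatedStudy(participants=participants, ema=ema, config=config,
                          generator_cutpoints=info["generator_cutpoints"],
                          clip_rates=info["clip_rates"])
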