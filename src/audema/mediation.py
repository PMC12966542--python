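"""Multilevel moderated mediation: does listening effort (or affect)
carry the within-person effect of auditory demand on fatigue?

Three linear mixed models are fitted on the identical complete-case set:

* **Model A** predicts the mediator from the demand components, z-scored
  PTA and the within-demand x PTA interaction (a-path, with its
  moderation), plus covariates;
* **Model B** predicts fatigue from the mediator components and the
  demand components (b-path and direct effect c');
* **Model C** predicts fatigue from the demand components alone (total
  effect c).

The indirect effect is the product of the within-person a and b
coefficients, with a 95% Monte-Carlo confidence interval from independent
normal draws of the two coefficients (default 4,000 draws).  Because
Model A contains the PTA interaction, a (and hence a x b) is evaluated at
the sample-mean moderator (PTA z = 0); the conditional indirect effect at
other hearing levels is available separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (ALPHA, DEFAULT_COVARIATES, DEMAND_COLUMNS, FitResult,
                     ModelSpec, fit_mixed_model, prepare_model_frame)

logger = logging.getLogger(__name__)

DEFAULT_DRAWS = 4000

PATTERNS = ("no mediation", "partial", "full/attenuated", "suppression")


@dataclass
class MediationConfig:
    draws: int = DEFAULT_DRAWS
    seed: int = 0
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    interaction: bool = True
    # include the other demand definitions' components in Model B
    # (supplementary-model variant); default: focal demand only
    include_other_demands: bool = False
    alpha: float = ALPHA


@dataclass
class MediationResult:
    demand: str
    mediator: str
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    c_prime: float
    indirect: float                  # a * b exactly
    indirect_ci: tuple[float, float]
    a_moderation: float              # demand_wp x PTA_z slope in Model A
    se_a_moderation: float
    draws: int
    seed: int
    pattern: str
    n_obs: int
    model_a: FitResult = field(repr=False, default=None)
    model_b: FitResult = field(repr=False, default=None)
    model_c: FitResult = field(repr=False, default=None)

    def to_table(self) -> pd.DataFrame:
        """Path-effect summary shaped like a mediation report table."""
        rows = [
            ("a (X->M)", self.a, *_wald_ci(self.a, self.se_a),
             self.model_a.p(self._dwp)),
            ("b (M->Y)", self.b, *_wald_ci(self.b, self.se_b),
             self.model_b.p(self._mwp)),
            ("Indirect a x b", self.indirect, *self.indirect_ci, np.nan),
            ("Direct c' (X->Y|M)", self.c_prime,
             *_wald_ci(self.c_prime, self.model_b.se(self._dwp)),
             self.model_b.p(self._dwp)),
            ("Total c (X->Y)", self.c,
             *_wald_ci(self.c, self.model_c.se(self._dwp)),
             self.model_c.p(self._dwp)),
            ("a-path PTA moderation", self.a_moderation,
             *_wald_ci(self.a_moderation, self.se_a_moderation),
             self.model_a.p(self._int)),
        ]
        return pd.DataFrame(rows, columns=["effect", "estimate",
                                           "ci_lower", "ci_upper", "p"])

    @property
    def _dwp(self) -> str:
        return f"{DEMAND_COLUMNS[self.demand]}_wp"

    @property
    def _mwp(self) -> str:
        return f"{self.mediator}_wp"

    @property
    def _int(self) -> str:
        return f"{self._dwp}:pta_z"


def _wald_ci(beta: float, se: float) -> tuple[float, float]:
    return beta - 1.96 * se, beta + 1.96 * se


def monte_carlo_indirect(a: float, se_a: float, b: float, se_b: float,
                         draws: int = DEFAULT_DRAWS,
                         seed: int | np.random.Generator = 0,
                         ) -> tuple[float, tuple[float, float]]:
    """Point estimate a*b and its Monte-Carlo 95% CI.

    Draws a* ~ N(a, se_a^2) and b* ~ N(b, se_b^2) independently (the two
    coefficients come from different fitted models) and takes the
    2.5/97.5 empirical percentiles of the products.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be >= 0")
    if draws < 1000:
        raise ValueError("use at least 1000 Monte-Carlo draws")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    prod = rng.normal(a, se_a, draws) * rng.normal(b, se_b, draws)
    lo, hi = np.percentile(prod, [2.5, 97.5])
    return a * b, (float(lo), float(hi))


def classify_pattern(c: float, c_p: float, c_prime: float, c_prime_p: float,
                     indirect_ci: tuple[float, float],
                     alpha: float = ALPHA) -> str:
    """Label the mediation pattern.

    The indirect CI covering zero means no mediation; otherwise a
    significant direct effect with sign opposite to the indirect effect is
    suppression (inconsistent mediation), a nonsignificant direct effect
    is full/attenuated mediation, and a significant same-sign direct
    effect is partial mediation.
    """
    lo, hi = indirect_ci
    if lo <= 0 <= hi:
        return "no mediation"
    indirect_sign = np.sign(lo + hi)
    if c_prime_p < alpha and np.sign(c_prime) == -indirect_sign:
        return "suppression"
    if c_prime_p >= alpha:
        return "full/attenuated"
    return "partial"


def _complete_case_frame(scored: pd.DataFrame, demand: str, mediator: str,
                         config: MediationConfig) -> pd.DataFrame:
    """The shared complete-case model frame for Models A, B and C."""
    extra = [f"{mediator}_wp", f"{mediator}_bp", "fatigue"]
    if config.include_other_demands:
        for other in DEMAND_COLUMNS:
            if other != demand:
                extra += [f"{DEMAND_COLUMNS[other]}_wp",
                          f"{DEMAND_COLUMNS[other]}_bp"]
    spec = ModelSpec(outcome=mediator, demand=demand,
                     covariates=config.covariates,
                     interaction=config.interaction)
    df, pta_std = prepare_model_frame(scored, spec, extra_cols=extra)
    df.attrs["pta_scaling"] = pta_std
    return df


def _demand_terms(demand: str, config: MediationConfig,
                  with_interaction: bool) -> list[str]:
    d = DEMAND_COLUMNS[demand]
    terms = [f"{d}_wp", f"{d}_bp", "pta_z"]
    if with_interaction:
        terms.append(f"{d}_wp:pta_z")
    if config.include_other_demands:
        for other in DEMAND_COLUMNS:
            if other != demand:
                terms += [f"{DEMAND_COLUMNS[other]}_wp",
                          f"{DEMAND_COLUMNS[other]}_bp"]
    return terms + list(config.covariates)


def fit_model_a(frame: pd.DataFrame, demand: str, mediator: str,
                config: MediationConfig) -> FitResult:
    """a-path model: mediator ~ demand + PTA + demand_wp x PTA_z + covs."""
    d = DEMAND_COLUMNS[demand]
    terms = _demand_terms(demand, config, config.interaction)
    formula = f"{mediator} ~ " + " + ".join(terms)
    return fit_mixed_model(frame, formula, within_cols=[f"{d}_wp"],
                           pta_scaling=frame.attrs.get("pta_scaling"))


def fit_model_b(frame: pd.DataFrame, demand: str, mediator: str,
                config: MediationConfig) -> FitResult:
    """b-path/direct model: fatigue ~ mediator + demand (+ interaction)."""
    d = DEMAND_COLUMNS[demand]
    terms = ([f"{mediator}_wp", f"{mediator}_bp"]
             + _demand_terms(demand, config, config.interaction))
    formula = "fatigue ~ " + " + ".join(terms)
    return fit_mixed_model(frame, formula,
                           within_cols=[f"{d}_wp", f"{mediator}_wp"],
                           pta_scaling=frame.attrs.get("pta_scaling"))


def fit_model_c(frame: pd.DataFrame, demand: str,
                config: MediationConfig) -> FitResult:
    """Total-effect model: fatigue ~ demand (+ interaction) + covariates."""
    d = DEMAND_COLUMNS[demand]
    terms = _demand_terms(demand, config, config.interaction)
    formula = "fatigue ~ " + " + ".join(terms)
    return fit_mixed_model(frame, formula, within_cols=[f"{d}_wp"],
                           pta_scaling=frame.attrs.get("pta_scaling"))


def conditional_indirect(result: MediationResult,
                         pta_z_values=(-1.0, 0.0, 1.0),
                         ) -> pd.DataFrame:
    """Conditional indirect effect (a + a_mod * PTA_z) * b over PTA levels."""
    rows = [{"pta_z": z,
             "indirect": (result.a + result.a_moderation * z) * result.b}
            for z in pta_z_values]
    return pd.DataFrame(rows)


def run_mediation(scored: pd.DataFrame, demand: str, mediator: str,
                  config: MediationConfig | None = None) -> MediationResult:
    """Full mediation analysis for one demand definition and mediator.

    All three models are fitted on the identical row set; the row counts
    are asserted equal.  `mediator` is "effort" or "affect"; the outcome
    is always momentary fatigue.
    """
    config = config or MediationConfig()
    if mediator not in ("effort", "affect"):
        raise ValueError("mediator must be 'effort' or 'affect'")
    logger.info("mediation %s -> %s: Model B uses %s demand components",
                demand, mediator,
                "all" if config.include_other_demands else "focal-only")
    frame = _complete_case_frame(scored, demand, mediator, config)

    ma = fit_model_a(frame, demand, mediator, config)
    mb = fit_model_b(frame, demand, mediator, config)
    mc = fit_model_c(frame, demand, config)
    assert ma.n_obs == mb.n_obs == mc.n_obs, \
        "Models A/B/C must share the same analysis rows"

    dwp = f"{DEMAND_COLUMNS[demand]}_wp"
    mwp = f"{mediator}_wp"
    interaction = f"{dwp}:pta_z"
    a, se_a = ma.beta(dwp), ma.se(dwp)
    b, se_b = mb.beta(mwp), mb.se(mwp)
    c_prime = mb.beta(dwp)
    c = mc.beta(dwp)
    if config.interaction:
        a_mod, se_a_mod = ma.beta(interaction), ma.se(interaction)
    else:
        a_mod, se_a_mod = np.nan, np.nan

    indirect, ci = monte_carlo_indirect(a, se_a, b, se_b,
                                        draws=config.draws, seed=config.seed)
    pattern = classify_pattern(c, mc.p(dwp), c_prime, mb.p(dwp), ci,
                               alpha=config.alpha)
    return MediationResult(
        demand=demand, mediator=mediator,
        a=a, se_a=se_a, b=b, se_b=se_b, c=c, c_prime=c_prime,
        indirect=indirect, indirect_ci=ci,
        a_moderation=a_mod, se_a_moderation=se_a_mod,
        draws=config.draws, seed=config.seed, pattern=pattern,
        n_obs=ma.n_obs, model_a=ma, model_b=mb, model_c=mc)
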