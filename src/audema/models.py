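"""Linear mixed-effects moderation models and person-level regressions.

The central model family regresses a momentary outcome (listening effort,
affect or fatigue) on one auditory-demand definition split into
within-person and between-person components, the z-scored pure-tone
average (PTA), the within-person demand x PTA interaction (the moderation
of interest), and the fixed covariate set (time of day, mean sleep
quality, mean sleep hours, age, sex) in original units, with a participant
random intercept, estimated by REML.  Fixed-effect confidence intervals
and p-values use the Wald normal approximation; results are flagged
significant at alpha = .01.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .decompose import StandardizedModerator, zscore

logger = logging.getLogger(__name__)

ALPHA = 0.01
Z_95 = 1.96  # conventional two-sided 95% normal quantile

DEFAULT_COVARIATES = ("time_of_day", "sleep_quality", "sleep_hours",
                      "age", "sex")

DEMAND_COLUMNS = {
    "environmental": "environmental_demand",
    "social": "social_demand",
    "subjective": "subjective_demand",
}


@dataclass
class ModelSpec:
    """Specification of one moderation model."""

    outcome: str                       # effort | affect | fatigue
    demand: str                        # environmental | social | subjective
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    interaction: bool = True           # within-demand x PTA(z)
    reml: bool = True
    # random slope for the within-person demand component; the default
    # (intercept only) is the minimal structure the analysis assumes
    random_slope: bool = False

    def __post_init__(self) -> None:
        if self.demand not in DEMAND_COLUMNS:
            raise ValueError(f"unknown demand definition '{self.demand}'")


@dataclass
class FitResult:
    """A fitted model: term-keyed coefficient table plus fit metadata."""

    coefficients: pd.DataFrame         # beta, se, ci_lower, ci_upper, t, p
    group_var: float
    residual_var: float
    n_obs: int
    n_groups: int
    converged: bool
    pta_scaling: StandardizedModerator | None = None
    extra: dict = field(default_factory=dict)

    def beta(self, term: str) -> float:
        return float(self.coefficients.loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.coefficients.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])


def coefficient_table(params: pd.Series, bse: pd.Series) -> pd.DataFrame:
    """Wald-style coefficient table (95% normal CIs, two-sided p)."""
    beta = np.asarray(params, dtype=float)
    se = np.asarray(bse, dtype=float)
    t = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(t))
    return pd.DataFrame({
        "beta": beta, "se": se,
        "ci_lower": beta - Z_95 * se, "ci_upper": beta + Z_95 * se,
        "t": t, "p": p, "significant": p < ALPHA,
    }, index=list(params.index))


def _check_within_centered(df: pd.DataFrame, cols) -> None:
    """Reject columns flagged as within-person that are not person-centered."""
    for col in cols:
        sums = df.groupby("participant_id")[col].sum().abs()
        counts = df.groupby("participant_id")[col].count()
        bad = sums > 1e-6 * counts.clip(lower=1)
        if bad.any():
            raise ValueError(
                f"column '{col}' is flagged within-person but does not sum "
                f"to zero within participant(s) {list(sums[bad].index[:3])}; "
                "person-mean center it first")


def fit_mixed_model(data: pd.DataFrame, formula: str,
                    within_cols=(), reml: bool = True,
                    pta_scaling: StandardizedModerator | None = None,
                    re_formula: str | None = None,
                    ) -> FitResult:
    """Fit a participant-random-intercept linear mixed model by REML.

    `data` must be complete cases for all model variables.  A singular
    random-intercept variance triggers a warning and is reported as zero;
    a rank-deficient fixed-effects design raises with the collinear
    term(s) named.
    """
    if len(within_cols):
        _check_within_centered(data, within_cols)
    n_groups = data["participant_id"].nunique()
    if n_groups < 2:
        raise ValueError("need >= 2 participants to fit a mixed model")

    model = smf.mixedlm(formula, data=data, groups=data["participant_id"],
                        re_formula=re_formula)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # name the terms whose removal restores full rank
        names = list(model.exog_names)
        collinear = []
        for j in range(model.exog.shape[1]):
            keep = [i for i in range(model.exog.shape[1]) if i != j]
            if np.linalg.matrix_rank(model.exog[:, keep]) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=reml, maxiter=500)
        except np.linalg.LinAlgError:
            logger.warning("default optimizer hit a singular system; "
                           "retrying with Powell")
            fit = model.fit(reml=reml, method="powell", maxiter=2000)

    group_var = float(np.asarray(fit.cov_re)[0, 0])
    if group_var < 1e-10 or not np.isfinite(group_var):
        logger.warning("random-intercept variance is singular (%.3g); "
                       "reporting 0", group_var)
        group_var = 0.0

    fe_names = list(model.exog_names)
    coefs = coefficient_table(fit.params[fe_names], fit.bse[fe_names])
    return FitResult(
        coefficients=coefs,
        group_var=group_var,
        residual_var=float(fit.scale),
        n_obs=int(fit.nobs),
        n_groups=int(n_groups),
        converged=bool(fit.converged),
        pta_scaling=pta_scaling,
    )


def prepare_model_frame(scored: pd.DataFrame, spec: ModelSpec,
                        extra_cols=()) -> tuple[pd.DataFrame, StandardizedModerator]:
    """Complete-case model frame with demand components and z-scored PTA.

    PTA is z-scored over the participants present in the analysis set, so
    the moderator's center/scale are recorded per fit.
    """
    demand = DEMAND_COLUMNS[spec.demand]
    cols = ([spec.outcome, f"{demand}_wp", f"{demand}_bp", "pta",
             "participant_id"] + list(spec.covariates) + list(extra_cols))
    if "time_of_day" in cols:
        scored = scored.assign(time_of_day=scored["timestamp_hours"])
    df = scored.loc[scored["answered"].astype(bool), cols].dropna()
    if df.empty:
        raise ValueError("no analyzable data: complete-case set is empty")
    per_person = df.groupby("participant_id")["pta"].first()
    pta_std = zscore(per_person)
    df = df.assign(pta_z=df["participant_id"].map(pta_std.z))
    return df, pta_std


def fit_moderation_model(scored: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit outcome ~ demand_wp + demand_bp + PTA_z (+ demand_wp:PTA_z)
    + covariates with a participant random intercept."""
    demand = DEMAND_COLUMNS[spec.demand]
    df, pta_std = prepare_model_frame(scored, spec)
    terms = [f"{demand}_wp", f"{demand}_bp", "pta_z"]
    if spec.interaction:
        terms.append(f"{demand}_wp:pta_z")
    terms += list(spec.covariates)
    formula = f"{spec.outcome} ~ " + " + ".join(terms)
    re_formula = f"~{demand}_wp" if spec.random_slope else None
    res = fit_mixed_model(df, formula, within_cols=[f"{demand}_wp"],
                          reml=spec.reml, pta_scaling=pta_std,
                          re_formula=re_formula)
    res.extra["spec"] = spec
    return res


@dataclass
class BetweenRegressionResult:
    """OLS of per-person mean demand on raw PTA (dB HL)."""

    slope: float
    se: float
    t: float
    p: float
    r_squared: float
    intercept: float
    n: int


def fit_between_regression(participants: pd.DataFrame, scored: pd.DataFrame,
                           demand: str = "subjective",
                           ) -> BetweenRegressionResult:
    """Person-level regression: mean demand ~ PTA in original dB HL units."""
    col = DEMAND_COLUMNS[demand]
    answered = scored[scored["answered"].astype(bool)]
    mean_demand = answered.groupby("participant_id")[col].mean()
    df = participants.set_index("participant_id").join(
        mean_demand.rename("mean_demand"), how="inner").dropna(
        subset=["mean_demand", "pta"])
    if len(df) < 3:
        raise ValueError("need >= 3 participants for the between regression")
    if df["pta"].std(ddof=1) == 0:
        raise ValueError("PTA has zero variance; slope undefined")
    X = sm.add_constant(df["pta"].to_numpy())
    fit = sm.OLS(df["mean_demand"].to_numpy(), X).fit()
    return BetweenRegressionResult(
        slope=float(fit.params[1]), se=float(fit.bse[1]),
        t=float(fit.tvalues[1]), p=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared), intercept=float(fit.params[0]),
        n=int(fit.nobs))
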