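"""Between- and within-subject correlation structure of the EMA measures.

Between-subject correlations are Pearson correlations across participants
of their study-period median values.  Within-subject structure is
summarised two ways: the elementwise median of per-participant
correlation matrices, and a variance-weighted Fisher-z pool (weights
n_i - 3) back-transformed to the correlation scale.  The between and
pooled-within matrices are contrasted cell by cell with two-sample
Fisher z-tests at alpha = .007 (multiple-testing control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: measures entering the correlation overview by default
DEFAULT_MEASURES = (
    "fatigue", "effort", "affect", "positive_affect", "negative_affect",
    "difficulty", "importance", "environmental_demand", "social_demand",
    "subjective_demand",
)

ALPHA_CONTRAST = 0.007

#: per-participant correlations need n >= 4 so the Fisher weight n-3 is positive
MIN_WITHIN_N = 4

WINSOR_R = 0.9999


def participant_medians(scored: pd.DataFrame,
                        measures=DEFAULT_MEASURES) -> pd.DataFrame:
    """Per-participant medians of each measure over answered prompts."""
    answered = scored[scored["answered"].astype(bool)]
    return answered.groupby("participant_id")[list(measures)].median()


def between_subject_matrix(scored: pd.DataFrame,
                           measures=DEFAULT_MEASURES) -> pd.DataFrame:
    """Pearson correlations of participant medians, pairwise-complete."""
    med = participant_medians(scored, measures)
    mat = med.corr(method="pearson", min_periods=3)
    for col in mat.columns:  # zero-variance medians yield undefined cells
        if med[col].std(ddof=1) == 0:
            logger.warning("between_subject_matrix: '%s' has zero variance "
                           "across participant medians; cells set missing", col)
    return mat


@dataclass
class WithinSubjectResult:
    median: pd.DataFrame        # elementwise median of per-person r
    pooled: pd.DataFrame        # back-transformed weighted Fisher-z pool
    pooled_z: pd.DataFrame      # the pooled z itself
    total_weight: pd.DataFrame  # sum of weights (n_i - 3) per cell
    n_participants: pd.DataFrame


def within_subject_matrices(scored: pd.DataFrame,
                            measures=DEFAULT_MEASURES,
                            min_n: int = MIN_WITHIN_N) -> WithinSubjectResult:
    """Median and variance-weighted pooled within-person correlations.

    A participant contributes to a cell only when they have at least
    `min_n` complete paired prompts for that pair; pooling weights are
    n_i - 3.  Perfect per-person correlations (|r| = 1, infinite Fisher z)
    are winsorized to +/-0.9999 and logged.
    """
    measures = list(measures)
    k = len(measures)
    answered = scored[scored["answered"].astype(bool)]
    r_stack, n_stack = [], []
    for _, grp in answered.groupby("participant_id"):
        vals = grp[measures].to_numpy(dtype=float)
        r = np.full((k, k), np.nan)
        n = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                pair = vals[:, [i, j]]
                ok = ~np.isnan(pair).any(axis=1)
                nij = int(ok.sum())
                n[i, j] = n[j, i] = nij
                if i == j:
                    r[i, j] = 1.0
                    continue
                if nij < min_n:
                    continue
                x, y = pair[ok, 0], pair[ok, 1]
                if x.std() == 0 or y.std() == 0:
                    continue
                rij = float(np.corrcoef(x, y)[0, 1])
                r[i, j] = r[j, i] = rij
        r_stack.append(r)
        n_stack.append(n)

    R = np.array(r_stack)          # participants x k x k
    N = np.array(n_stack)
    usable = ~np.isnan(R) & (N >= min_n)
    off = ~np.eye(k, dtype=bool)

    masked = np.where(usable, R, np.nan).reshape(len(R), k * k)
    any_usable = usable.any(axis=0).ravel()
    median = np.full(k * k, np.nan)
    if any_usable.any():
        median[any_usable] = np.nanmedian(masked[:, any_usable], axis=0)
    median = median.reshape(k, k)

    Rw = np.clip(R, -WINSOR_R, WINSOR_R)
    n_winsor = int((usable & off & (np.abs(R) >= 1.0)).sum()) // 2
    if n_winsor:
        logger.info("within_subject_matrices: winsorized %d perfect "
                    "per-person correlation(s) to +/-%.4f", n_winsor, WINSOR_R)
    W = np.where(usable, N - 3.0, 0.0)
    Z = np.where(usable, np.arctanh(np.where(usable, Rw, 0.0)), 0.0)
    wsum = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_z = np.where(wsum > 0, (W * Z).sum(axis=0) / wsum, np.nan)
    pooled = np.tanh(pooled_z)
    np.fill_diagonal(pooled, 1.0)
    np.fill_diagonal(median, 1.0)

    def _df(a):
        return pd.DataFrame(a, index=measures, columns=measures)

    return WithinSubjectResult(
        median=_df(median), pooled=_df(pooled), pooled_z=_df(pooled_z),
        total_weight=_df(wsum), n_participants=_df(usable.sum(axis=0)))


@dataclass
class CorrelationContrast:
    """A between- vs within-subject contrast for one variable pair."""

    pair: tuple[str, str]
    r_between: float
    r_within_median: float
    r_within_pooled: float
    z_stat: float
    p_value: float
    significant: bool


def contrast_between_within(r_between: float, n_between: int,
                            pooled_z: float, total_weight: float,
                            pair=("x", "y"),
                            r_within_median: float = np.nan,
                            alpha: float = ALPHA_CONTRAST,
                            ) -> CorrelationContrast | None:
    """Two-sample Fisher z-test of a between vs pooled-within correlation.

    z = (atanh(r_b) - z_w) / sqrt(1/(n_b - 3) + 1/sum(w_i)); the pooled
    weight plays the role of an effective n - 3.  Returns None (with a
    log entry) when any input is non-finite.
    """
    if n_between < 4:
        raise ValueError("contrast needs n_between >= 4")
    inputs = (r_between, pooled_z, total_weight)
    if not all(np.isfinite(v) for v in inputs) or total_weight <= 0:
        logger.info("contrast %s skipped: non-finite inputs %s", pair, inputs)
        return None
    zb = np.arctanh(np.clip(r_between, -WINSOR_R, WINSOR_R))
    se = np.sqrt(1.0 / (n_between - 3) + 1.0 / total_weight)
    z_stat = float((zb - pooled_z) / se)
    p = float(2 * stats.norm.sf(abs(z_stat)))
    return CorrelationContrast(
        pair=tuple(pair), r_between=float(r_between),
        r_within_median=float(r_within_median),
        r_within_pooled=float(np.tanh(pooled_z)),
        z_stat=z_stat, p_value=p, significant=p < alpha)


def contrast_table(scored: pd.DataFrame, measures=DEFAULT_MEASURES,
                   min_n: int = MIN_WITHIN_N,
                   alpha: float = ALPHA_CONTRAST) -> pd.DataFrame:
    """All pairwise between-vs-within contrasts as a tidy table."""
    measures = list(measures)
    between = between_subject_matrix(scored, measures)
    med = participant_medians(scored, measures)
    within = within_subject_matrices(scored, measures, min_n)
    rows = []
    for i, a in enumerate(measures):
        for b in measures[i + 1:]:
            n_b = int(med[[a, b]].dropna().shape[0])
            res = None
            if n_b >= 4:
                res = contrast_between_within(
                    between.loc[a, b], n_b,
                    within.pooled_z.loc[a, b],
                    within.total_weight.loc[a, b],
                    pair=(a, b),
                    r_within_median=within.median.loc[a, b],
                    alpha=alpha)
            if res is None:
                rows.append({"var1": a, "var2": b, "r_between": np.nan,
                             "r_within_median": np.nan,
                             "r_within_pooled": np.nan, "z_stat": np.nan,
                             "p_value": np.nan, "significant": False})
            else:
                rows.append({"var1": a, "var2": b,
                             "r_between": res.r_between,
                             "r_within_median": res.r_within_median,
                             "r_within_pooled": res.r_within_pooled,
                             "z_stat": res.z_stat, "p_value": res.p_value,
                             "significant": res.significant})
    return pd.DataFrame(rows)
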