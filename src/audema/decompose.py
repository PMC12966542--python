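"""Within/between decomposition of time-varying predictors and
standardization of person-level moderators.

The mixed models require each momentary predictor split into a
within-person component (deviation from that participant's own mean,
person-mean centering) and a between-person component (the participant's
mean, grand-mean centered).  The grand mean is taken over person means
unweighted by prompt count: the between component is a person-level
quantity, so every participant contributes equally regardless of how many
prompts they answered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DecomposedPredictor:
    """One predictor split into components, row-aligned with its source."""

    within: pd.Series          # per-row deviation from the person mean
    between: pd.Series         # person mean, grand-mean centered (per row)
    person_mean: pd.Series     # raw person mean, indexed by participant
    grand_mean: float


@dataclass
class StandardizedModerator:
    """A z-scored person-level variable with its back-transform."""

    z: pd.Series
    center: float
    scale: float

    def inverse(self, z_value: float) -> float:
        """Raw-unit value at a given z (e.g. the moderator at +/-1 SD)."""
        return z_value * self.scale + self.center


def person_center(values: pd.Series, participant: pd.Series,
                  ) -> DecomposedPredictor:
    """Person-mean center a momentary variable.

    Means use available (non-missing) observations only; participants
    with no usable observation are excluded (their rows stay missing) and
    logged.  At every observed row, within + person_mean reconstructs the
    raw value exactly.
    """
    values = pd.Series(np.asarray(values, dtype=float),
                       index=participant.index)
    means = values.groupby(participant).mean()
    dropped = means[means.isna()]
    if len(dropped):
        logger.info("person_center: %d participant(s) with no usable "
                    "observations excluded: %s", len(dropped),
                    list(dropped.index[:5]))
        means = means.dropna()
    grand = float(means.mean())
    pm_rows = participant.map(means)
    return DecomposedPredictor(
        within=values - pm_rows,
        between=pm_rows - grand,
        person_mean=means,
        grand_mean=grand,
    )


def zscore(values: pd.Series) -> StandardizedModerator:
    """Standardize a person-level variable (sample SD, n-1 denominator)."""
    arr = pd.Series(np.asarray(values, dtype=float), index=values.index)
    center = float(arr.mean())
    scale = float(arr.std(ddof=1))
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError("cannot z-score a variable with zero variance")
    return StandardizedModerator(z=(arr - center) / scale,
                                 center=center, scale=scale)


#: momentary variables decomposed by default before modeling
DEFAULT_WITHIN_VARS = ("environmental_demand", "social_demand",
                       "subjective_demand", "effort", "affect")


def add_decomposition(scored: pd.DataFrame,
                      columns=DEFAULT_WITHIN_VARS) -> pd.DataFrame:
    """Append `_wp` (within) and `_bp` (between) columns for each variable."""
    out = scored.copy()
    for col in columns:
        dec = person_center(out[col], out["participant_id"])
        out[f"{col}_wp"] = dec.within
        out[f"{col}_bp"] = dec.between
    return out
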