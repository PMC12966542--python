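"""Reduction of raw EMA items to derived analysis variables.

Three auditory-demand scores are produced per answered prompt:

* **environmental** (0-3) from the multi-select "listening situation" item,
  following the Common Sound Scenarios regrouping: passive listening /
  ambient noise (0) < active listening (1) < conversation with one person
  (2) < conversation with more than one person (3);
* **social** (0-2) from the multi-select "who were you with" item:
  alone (0) < family, i.e. partner or children (1) < anyone else (2);
* **subjective** (0-2): tertile rank of the difficulty x importance
  product (each item ordinal 1-5, product 1-25), motivated by the FUEL
  framework's view of effort as demand x motivation.

Multi-select answers are reduced with the *highest-demand-selected* rule:
the score of a combination is the maximum base score among its options,
which reproduces every singleton assignment and is monotone under set
inclusion.  Affect is summarised by the mean of the four positive and five
negative mood sliders plus the single "feeling now" item (0-10), which is
the primary affect variable downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = float("nan")

#: base environmental-demand score per listening-situation option
SITUATION_SCORES: dict[str, int] = {
    "Passive listening, not an active listening task": 0,
    "Ambient noise": 0,
    "Actively listening to a speaker (live)": 1,
    "Actively listening to TV, radio, etc.": 1,
    "Conversation with 1 person": 2,
    "Phone conversation": 2,
    "Conversation with more than 1 person": 3,
}

#: base social-demand score per who-with option
WHO_WITH_SCORES: dict[str, int] = {
    "Alone": 0,
    "Partner": 1,
    "Children": 1,
    "One or more colleagues": 2,
    "Family (besides your partner and children)": 2,
    "Friend(s)": 2,
    "Other": 2,
}

#: version tag for the label -> score mapping, recorded in run sidecars
LABEL_MAP_VERSION = "1"

MULTI_SELECT_SEP = ";"


def _score_selection(selection: Iterable[str] | str | float,
                     table: dict[str, int], item: str) -> float:
    """Max base score of a multi-select answer; NaN for an empty answer."""
    if isinstance(selection, float) and math.isnan(selection):
        return MISSING
    if isinstance(selection, str):
        labels = [s for s in selection.split(MULTI_SELECT_SEP) if s]
    else:
        labels = list(selection)
    if not labels:
        return MISSING
    unknown = [lab for lab in labels if lab not in table]
    if unknown:
        raise ValueError(
            f"unknown {item} label(s) {unknown!r}; "
            f"valid labels: {sorted(table)}")
    return float(max(table[lab] for lab in labels))


def score_environmental(situation: Iterable[str] | str) -> float:
    """Environmental auditory demand (0-3) of a listening-situation answer."""
    return _score_selection(situation, SITUATION_SCORES, "listening situation")


def score_social(who_with: Iterable[str] | str) -> float:
    """Social auditory demand (0-2) of a who-were-you-with answer."""
    return _score_selection(who_with, WHO_WITH_SCORES, "who with")


def subjective_product(difficulty: int, importance: int) -> int:
    """Difficulty x importance product (1-25) from the two ordinal items."""
    d, i = int(difficulty), int(importance)
    if not (1 <= d <= 5) or not (1 <= i <= 5):
        raise ValueError(
            f"difficulty/importance must be in 1..5, got ({difficulty}, {importance})")
    return d * i


@dataclass(frozen=True)
class TertileCutpoints:
    """Empirical tertile cutpoints of the pooled difficulty x importance
    product; a score <= `lower` ranks 0, <= `upper` ranks 1, else 2."""

    lower: float
    upper: float
    source_n: int

    def __post_init__(self) -> None:
        if not (1 <= self.lower <= self.upper <= 25):
            raise ValueError(
                f"cutpoints must satisfy 1 <= lower <= upper <= 25, "
                f"got ({self.lower}, {self.upper})")


def fit_tertiles(products: Iterable[int]) -> TertileCutpoints:
    """Tertile cutpoints of the observed product distribution.

    Quantiles use the inverse empirical CDF (R type 1) so that cutpoints
    are observed values; ties fall in the lower rank.
    """
    arr = np.asarray(list(products), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise ValueError(f"need >= 3 products to fit tertiles, got {arr.size}")
    lower, upper = np.quantile(arr, [1 / 3, 2 / 3], method="inverted_cdf")
    if lower == upper:
        logger.warning(
            "degenerate tertile cutpoints (lower == upper == %s); "
            "subjective ranks will collapse", lower)
    return TertileCutpoints(float(lower), float(upper), int(arr.size))


def score_subjective(product: float, cuts: TertileCutpoints) -> float:
    """Subjective auditory demand rank (0-2) of a product given cutpoints."""
    if isinstance(product, float) and math.isnan(product):
        return MISSING
    if not (1 <= product <= 25):
        raise ValueError(f"product must be in 1..25, got {product}")
    if product <= cuts.lower:
        return 0.0
    if product <= cuts.upper:
        return 1.0
    return 2.0


def affect_scores(positive_items: Iterable[float],
                  negative_items: Iterable[float],
                  feeling_now: float) -> tuple[float, float, float]:
    """(positive, negative, affect) summaries for one prompt.

    Positive/negative affect are item means (1-7 sliders); a mean is
    computed when at least half the items are present, else missing.  The
    primary affect variable is the "feeling now" item (0-10) unchanged.
    """

    def _mean(items: Iterable[float], n_items: int) -> float:
        vals = np.asarray(list(items), dtype=float)
        present = vals[~np.isnan(vals)]
        if present.size * 2 < n_items:
            return MISSING
        return float(present.mean())

    pos = _mean(positive_items, 4)
    neg = _mean(negative_items, 5)
    return pos, neg, float(feeling_now)


# ----------------------------------------------------------------------
# table-level scoring

POSITIVE_COLS = [f"pos{i}" for i in range(1, 5)]
NEGATIVE_COLS = [f"neg{i}" for i in range(1, 6)]


def score_table(ema: pd.DataFrame,
                cuts: TertileCutpoints | None = None,
                ) -> tuple[pd.DataFrame, TertileCutpoints]:
    """Append derived-variable columns to an EMA long table.

    Adds environmental_demand, social_demand, difficulty_importance_product,
    subjective_demand, positive_affect, negative_affect and affect.  Rows
    with ``answered == False`` score as missing.  Tertile cutpoints are
    fitted on the pooled answered products unless supplied.
    """
    out = ema.copy()
    answered = out["answered"].astype(bool)
    if not answered.any():
        raise ValueError("no answered prompts: no analyzable data to score")

    def _col(name: str, func) -> pd.Series:
        vals = np.full(len(out), np.nan)
        idx = np.flatnonzero(answered.to_numpy())
        col = out[name].to_numpy(dtype=object)
        for i in idx:
            vals[i] = func(col[i])
        return pd.Series(vals, index=out.index)

    out["environmental_demand"] = _col("situation", score_environmental)
    out["social_demand"] = _col("who_with", score_social)

    prod = np.full(len(out), np.nan)
    diff = out["difficulty"].to_numpy(dtype=float)
    imp = out["importance"].to_numpy(dtype=float)
    mask = answered.to_numpy() & ~np.isnan(diff) & ~np.isnan(imp)
    prod[mask] = diff[mask] * imp[mask]
    out["difficulty_importance_product"] = prod

    if cuts is None:
        cuts = fit_tertiles(prod[mask])
    subj = np.full(len(out), np.nan)
    subj[mask & (prod <= cuts.lower)] = 0.0
    subj[mask & (prod > cuts.lower) & (prod <= cuts.upper)] = 1.0
    subj[mask & (prod > cuts.upper)] = 2.0
    out["subjective_demand"] = subj

    def _item_mean(cols: list[str], n_items: int) -> np.ndarray:
        vals = out[cols].to_numpy(dtype=float)
        present = ~np.isnan(vals)
        n = present.sum(axis=1)
        total = np.where(present, vals, 0.0).sum(axis=1)
        mean = np.divide(total, n, out=np.full(len(out), np.nan), where=n > 0)
        mean[n * 2 < n_items] = np.nan
        return mean

    pos_mean = _item_mean(POSITIVE_COLS, 4)
    neg_mean = _item_mean(NEGATIVE_COLS, 5)
    out["positive_affect"] = np.where(answered, pos_mean, np.nan)
    out["negative_affect"] = np.where(answered, neg_mean, np.nan)
    out["affect"] = np.where(answered, out["feeling_now"], np.nan)
    return out, cuts
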