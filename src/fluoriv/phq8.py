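"""PHQ-8 depression scale scoring.

The eight-item Patient Health Questionnaire asks, for each symptom, on how
many of the past 14 days it was experienced. Day counts are converted to item
scores 0-3 ("not at all" ... "nearly every day"); the total (0-24) is used
continuously and dichotomised at >=10 for probable major depression.

The day->score thresholds are configurable; the default is the BRFSS/PHQ-8
convention: 0-1 days -> 0, 2-6 -> 1, 7-11 -> 2, 12-14 -> 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_DAYS = 14
N_ITEMS = 8
CASENESS_CUTOFF = 10
ITEM_COLUMNS = tuple(f"phq{i}" for i in range(1, N_ITEMS + 1))


class PHQValidationError(ValueError):
    """Raised for day counts outside [0, 14] or malformed responses."""


@dataclass(frozen=True)
class DayMapping:
    """Thresholds partitioning day counts 0-14 into item scores 0-3.

    ``upper_bounds[k]`` is the largest day count mapped to score ``k``;
    the last bound must be 14 so every legal count has exactly one score.
    """

    upper_bounds: tuple[int, int, int, int] = (1, 6, 11, 14)

    def __post_init__(self):
        ub = self.upper_bounds
        if len(ub) != 4 or list(ub) != sorted(set(ub)) or ub[-1] != MAX_DAYS:
            raise PHQValidationError(
                f"upper_bounds must be 4 strictly increasing ints ending at "
                f"{MAX_DAYS}, got {ub}"
            )
        if ub[0] < 0:
            raise PHQValidationError("thresholds must be non-negative")

    def score_days(self, days):
        """Map day counts (scalar or array) to item scores 0-3."""
        arr = np.asarray(days)
        if np.any((arr < 0) | (arr > MAX_DAYS)):
            raise PHQValidationError(
                f"day counts must lie in [0, {MAX_DAYS}]; got values outside"
            )
        scores = np.searchsorted(np.asarray(self.upper_bounds), arr, side="left")
        return scores if scores.ndim else int(scores)


DEFAULT_MAPPING = DayMapping()


@dataclass(frozen=True)
class PHQ8Score:
    item_scores: tuple[int, ...]
    total: int
    probable_major_depression: bool


def score_item(days: int, mapping: DayMapping = DEFAULT_MAPPING) -> int:
    """Score a single item's day count on the 0-3 scale."""
    return mapping.score_days(days)


def score_total(days_by_item, mapping: DayMapping = DEFAULT_MAPPING) -> PHQ8Score:
    """Score one complete 8-item response."""
    arr = np.asarray(days_by_item, dtype=float)
    if arr.shape != (N_ITEMS,):
        raise PHQValidationError(f"expected {N_ITEMS} items, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise PHQValidationError("missing PHQ item; respondent must be excluded")
    items = tuple(int(s) for s in mapping.score_days(arr.astype(int)))
    total = int(sum(items))
    return PHQ8Score(items, total, total >= CASENESS_CUTOFF)


def score_frame(
    survey: pd.DataFrame, mapping: DayMapping = DEFAULT_MAPPING
) -> pd.DataFrame:
    """Score all respondents in a survey table.

    Returns a frame aligned to ``survey`` with per-item score columns
    ``phq1_score``..``phq8_score``, ``phq_total``, ``phq_case`` and a boolean
    ``phq_complete`` flag; respondents with any missing or out-of-range item
    get ``phq_complete=False`` and NaN scores (complete-case exclusion happens
    downstream).
    """
    missing_cols = set(ITEM_COLUMNS) - set(survey.columns)
    if missing_cols:
        raise PHQValidationError(f"survey missing PHQ columns: {sorted(missing_cols)}")
    days = survey[list(ITEM_COLUMNS)].apply(pd.to_numeric, errors="coerce").to_numpy()
    legal = (days >= 0) & (days <= MAX_DAYS) & ~np.isnan(days)
    complete = legal.all(axis=1)

    scores = np.full(days.shape, np.nan)
    if complete.any():
        scores[complete] = np.searchsorted(
            np.asarray(mapping.upper_bounds), days[complete], side="left"
        )
    out = pd.DataFrame(
        scores, columns=[f"{c}_score" for c in ITEM_COLUMNS], index=survey.index
    )
    out["phq_total"] = scores.sum(axis=1)
    out["phq_case"] = np.where(
        complete, (out["phq_total"] >= CASENESS_CUTOFF).astype(float), np.nan
    )
    out["phq_complete"] = complete
    return out
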