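"""Treatment coding for the four-bracket tooth-loss response.

BRFSS asks how many permanent teeth were removed for decay or gum disease,
with brackets None / 1-5 / 6 or more but not all / All. The main analysis
assigns each bracket the midpoint of its range in a 28-tooth mouth (wisdom
teeth excluded): 0, 3, 16.5, 28. Dichotomised contrasts and user-supplied
sensitivity value-sets re-use the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BRACKETS = ("none", "one_to_five", "six_plus_not_all", "all")
MIDPOINT_VALUES = (0.0, 3.0, 16.5, 28.0)
MAX_TEETH = 28.0


class CodingError(ValueError):
    """Raised for unknown bracket labels or non-monotone value sets."""


@dataclass(frozen=True)
class TreatmentCoding:
    """Named mapping from tooth-loss bracket to a continuous tooth count."""

    name: str = "midpoint"
    values: tuple[float, float, float, float] = MIDPOINT_VALUES

    def __post_init__(self):
        v = self.values
        if len(v) != len(BRACKETS):
            raise CodingError(f"need {len(BRACKETS)} values, got {len(v)}")
        if not all(a < b for a, b in zip(v, v[1:])):
            raise CodingError(f"bracket values must be strictly increasing: {v}")
        if v[0] < 0 or v[-1] > MAX_TEETH:
            raise CodingError(f"bracket values must lie in [0, {MAX_TEETH}]: {v}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(BRACKETS, self.values))


MIDPOINT_CODING = TreatmentCoding()


def _check_brackets(brackets) -> pd.Series:
    s = pd.Series(brackets)
    bad = ~s.isin(BRACKETS)
    if bad.any():
        raise CodingError(f"unknown bracket labels: {sorted(s[bad].unique())}")
    return s


def code_continuous(brackets, coding: TreatmentCoding = MIDPOINT_CODING) -> np.ndarray:
    """Map bracket labels to the coding's continuous tooth counts."""
    s = _check_brackets(brackets)
    return s.map(coding.as_dict()).to_numpy(dtype=float)


def code_binary(brackets, contrast: str) -> np.ndarray:
    """Dichotomise the bracket response.

    ``any_loss``: 1 for any tooth lost vs 0 for full dentition.
    ``edentulous``: 1 for all teeth lost vs 0 for partial loss; respondents
    with no tooth lost are outside the comparison group and coded NaN
    (an exclusion marker, dropped when the frame is assembled).
    """
    s = _check_brackets(brackets)
    if contrast == "any_loss":
        return (s != "none").to_numpy(dtype=float)
    if contrast == "edentulous":
        out = np.where(s == "all", 1.0, 0.0)
        out[(s == "none").to_numpy()] = np.nan
        return out
    raise CodingError(f"unknown contrast: {contrast!r}")


def sensitivity_codings(
    mean_values, median_values, mode_values
) -> list[TreatmentCoding]:
    """Build the mean/median/mode sensitivity codings from user-supplied values.

    The replacement values come from an external clinical-examination study
    and are configuration inputs, not constants of this package.
    """
    return [
        TreatmentCoding(name, tuple(float(v) for v in values))
        for name, values in (
            ("mean", mean_values),
            ("median", median_values),
            ("mode", mode_values),
        )
    ]


def bracket_from_count(counts) -> np.ndarray:
    """Assign the reporting bracket for integer tooth counts 0-28."""
    c = np.asarray(counts)
    if np.any((c < 0) | (c > 28)):
        raise CodingError("tooth counts must lie in [0, 28]")
    out = np.full(c.shape, "six_plus_not_all", dtype=object)
    out[c == 0] = "none"
    out[(c >= 1) & (c <= 5)] = "one_to_five"
    out[c == 28] = "all"
    return out
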