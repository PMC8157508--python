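"""Childhood water-fluoridation exposure instrument.

The instrument Z for a respondent is the county-level proportion of the
population supplied with fluoridated water, accumulated over the ten calendar
years in which the respondent was 5-14 years old (the window of post-eruptive
enamel maturation of the permanent teeth) and rescaled to [0, 1] by dividing
by 10:

    Z = (1/10) * sum_{a=5}^{14} proportion(county, birth_year + a)

Years before the first census year contribute 0 (pre-fluoridation era); years
after the last census year contribute the county's last observed proportion.
A (county, year) pair absent from the census within its span is treated as
proportion 0 (census files list served populations; absence means no
fluoridation) and a warning is logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CENSUS_COLUMNS = ("county_id", "year", "proportion_fluoridated")

#: age window (inclusive) over which childhood exposure accumulates
EXPOSURE_AGES = (5, 14)


class CensusValidationError(ValueError):
    """Raised when a fluoridation census table violates its schema."""


class UnknownCountyError(KeyError):
    """Raised when respondents reference counties absent from the census."""

    def __init__(self, counties):
        self.counties = sorted(counties)
        super().__init__(
            f"counties not present in the fluoridation census: {self.counties}"
        )


def validate_census(census: pd.DataFrame) -> pd.DataFrame:
    """Check schema, uniqueness and proportion bounds of a census table."""
    missing = set(CENSUS_COLUMNS) - set(census.columns)
    if missing:
        raise CensusValidationError(f"census table missing columns: {sorted(missing)}")
    if census.empty:
        raise CensusValidationError("census table is empty")
    if census.duplicated(["county_id", "year"]).any():
        dups = census[census.duplicated(["county_id", "year"], keep=False)]
        raise CensusValidationError(
            "duplicate (county, year) rows in census: "
            f"{dups[['county_id', 'year']].head().to_dict('records')}"
        )
    prop = pd.to_numeric(census["proportion_fluoridated"], errors="coerce")
    if prop.isna().any() or (prop < 0).any() or (prop > 1).any():
        bad = census.loc[prop.isna() | (prop < 0) | (prop > 1)]
        raise CensusValidationError(
            "proportion_fluoridated must be a number in [0, 1]; offending rows: "
            f"{bad.head().to_dict('records')}"
        )
    out = census.copy()
    out["proportion_fluoridated"] = prop.astype(float)
    out["year"] = out["year"].astype(int)
    return out


def load_census(path) -> pd.DataFrame:
    """Read and validate a census CSV (county_id, year, proportion_fluoridated)."""
    return validate_census(pd.read_csv(path))


def compute_exposure(census: pd.DataFrame, respondents: pd.DataFrame) -> pd.DataFrame:
    """Compute the exposure instrument for every respondent.

    Parameters
    ----------
    census
        Validated fluoridation census (one row per county-year).
    respondents
        Table with at least ``respondent_id``, ``birth_year`` and ``county_id``.

    Returns
    -------
    DataFrame with columns ``respondent_id`` and ``exposure_z`` (in [0, 1]),
    one row per input respondent, input order preserved.
    """
    census = validate_census(census)
    for col in ("respondent_id", "birth_year", "county_id"):
        if col not in respondents.columns:
            raise CensusValidationError(f"respondent table missing column: {col}")

    year_min = int(census["year"].min())
    year_max = int(census["year"].max())
    n_years = year_max - year_min + 1

    counties = pd.Index(census["county_id"].unique())
    unknown = set(respondents["county_id"].unique()) - set(counties)
    if unknown:
        raise UnknownCountyError(unknown)

    # dense county x year matrix; unobserved in-span cells default to 0
    mat = np.zeros((len(counties), n_years))
    observed = np.zeros((len(counties), n_years), dtype=bool)
    ci = counties.get_indexer(census["county_id"])
    yi = census["year"].to_numpy() - year_min
    mat[ci, yi] = census["proportion_fluoridated"].to_numpy()
    observed[ci, yi] = True
    n_missing = observed.size - observed.sum()
    if n_missing:
        logger.warning(
            "census has %d unobserved (county, year) cells within %d-%d; "
            "treated as proportion 0",
            n_missing,
            year_min,
            year_max,
        )

    birth = respondents["birth_year"].to_numpy(dtype=int)
    rci = counties.get_indexer(respondents["county_id"])
    ages = np.arange(EXPOSURE_AGES[0], EXPOSURE_AGES[1] + 1)
    years = birth[:, None] + ages[None, :]  # (n, 10) calendar years

    # boundary rule: clamp to span, then zero out pre-span years
    idx = np.clip(years, year_min, year_max) - year_min
    vals = mat[rci[:, None], idx]
    vals[years < year_min] = 0.0
    z = vals.sum(axis=1) / len(ages)

    return pd.DataFrame(
        {"respondent_id": respondents["respondent_id"].to_numpy(), "exposure_z": z}
    )


def write_exposure_csv(exposure: pd.DataFrame, path) -> None:
    exposure.to_csv(path, index=False)
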