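"""Study orchestration: frame assembly, main/stratified/sensitivity/item runs.

Reads the two input files (fluoridation census CSV, survey CSV), assembles
complete-case analysis frames with the covariate design (year-of-birth, survey
wave, gender, state), and runs the instrumental-variable analyses, emitting
result tables in which every second-stage estimate is accompanied by its
first-stage F and sample size, plus a full audit trail of exclusions and
settings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import coding as coding_mod
from . import exposure as exposure_mod
from . import phq8
from .iv import (
    AnalysisFrame,
    EstimationError,
    IVFit,
    WeakInstrumentError,
    build_covariate_design,
    fit_2sls,
    linear_probability_iv,
)

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = (
    "respondent_id",
    "birth_year",
    "wave",
    "gender",
    "state",
    "county_id",
    "teeth_bracket",
) + phq8.ITEM_COLUMNS

OUTCOMES = ("total", "caseness") + tuple(f"item{j}" for j in range(1, 9))
TREATMENTS = ("continuous", "any_loss", "edentulous")


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class StudyConfig:
    census_path: str
    survey_path: str
    cohort_range: tuple[int, int] = (1940, 1978)
    coding: coding_mod.TreatmentCoding = coding_mod.MIDPOINT_CODING
    sensitivity_codings: tuple[coding_mod.TreatmentCoding, ...] = ()
    day_mapping: phq8.DayMapping = phq8.DEFAULT_MAPPING
    se_type: str = "robust"
    birth_year_mode: str = "indicators"
    age_split: int = 50  # sample-mean age; printed in every report
    birth_year_split: int = 1959  # cohort midpoint
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "coding" in kwargs:
            kwargs["coding"] = coding_mod.TreatmentCoding(
                kwargs["coding"].get("name", "custom"),
                tuple(kwargs["coding"]["values"]),
            )
        if "sensitivity_codings" in kwargs:
            kwargs["sensitivity_codings"] = tuple(
                coding_mod.TreatmentCoding(c["name"], tuple(c["values"]))
                for c in kwargs["sensitivity_codings"]
            )
        if "day_mapping" in kwargs:
            kwargs["day_mapping"] = phq8.DayMapping(tuple(kwargs["day_mapping"]))
        for key in ("cohort_range",):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def settings_dict(self) -> dict:
        return {
            "cohort_range": list(self.cohort_range),
            "coding": {"name": self.coding.name, "values": list(self.coding.values)},
            "day_mapping": list(self.day_mapping.upper_bounds),
            "se_type": self.se_type,
            "birth_year_mode": self.birth_year_mode,
            "age_split": self.age_split,
            "birth_year_split": self.birth_year_split,
        }


@dataclass
class ExclusionLog:
    steps: list = field(default_factory=list)

    def record(self, step: str, removed: int, remaining: int) -> None:
        self.steps.append({"step": step, "removed": int(removed), "remaining": int(remaining)})
        if removed:
            logger.info("exclusion %-28s removed=%d remaining=%d", step, removed, remaining)

    def to_list(self) -> list:
        return list(self.steps)


def load_survey(path) -> pd.DataFrame:
    survey = pd.read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(survey.columns)
    if missing:
        raise SchemaError(f"survey file missing columns: {sorted(missing)}")
    return survey


def _outcome_column(outcome: str) -> str:
    if outcome == "total":
        return "phq_total"
    if outcome == "caseness":
        return "phq_case"
    if outcome.startswith("item"):
        j = int(outcome[4:])
        return f"phq{j}_score"
    raise SchemaError(f"unknown outcome: {outcome!r}")


def assemble_frame(
    census: pd.DataFrame,
    survey: pd.DataFrame,
    config: StudyConfig,
    treatment: str = "continuous",
    coding: Optional[coding_mod.TreatmentCoding] = None,
    outcome: str = "total",
    subset: Optional[np.ndarray] = None,
) -> tuple[AnalysisFrame, ExclusionLog]:
    """Join exposure, treatment coding, PHQ scores and covariates into a frame.

    Applies the birth-cohort filter and complete-case exclusions, logging the
    row count removed at every step.
    """
    if treatment not in TREATMENTS:
        raise SchemaError(f"unknown treatment: {treatment!r}")
    coding = coding or config.coding
    log = ExclusionLog()
    df = survey.reset_index(drop=True)
    log.record("input rows", 0, len(df))

    if subset is not None:
        keep = np.asarray(subset, dtype=bool)
        df = df.loc[keep].reset_index(drop=True)
        log.record("stratum restriction", int((~keep).sum()), len(df))

    lo, hi = config.cohort_range
    in_cohort = df["birth_year"].between(lo, hi)
    df = df.loc[in_cohort].reset_index(drop=True)
    log.record(f"birth cohort {lo}-{hi}", int((~in_cohort).sum()), len(df))

    scores = phq8.score_frame(df, config.day_mapping)
    complete = scores["phq_complete"].to_numpy()
    df = pd.concat([df, scores], axis=1).loc[complete].reset_index(drop=True)
    log.record("complete PHQ-8 items", int((~complete).sum()), len(df))

    valid_bracket = df["teeth_bracket"].isin(coding_mod.BRACKETS)
    df = df.loc[valid_bracket].reset_index(drop=True)
    log.record("valid tooth-loss bracket", int((~valid_bracket).sum()), len(df))

    if treatment == "continuous":
        t = coding_mod.code_continuous(df["teeth_bracket"], coding)
    else:
        t = coding_mod.code_binary(df["teeth_bracket"], treatment)
        in_contrast = ~np.isnan(t)
        df = df.loc[in_contrast].reset_index(drop=True)
        t = t[in_contrast]
        log.record(f"{treatment} comparison group", int((~in_contrast).sum()), len(df))

    if df.empty:
        raise EstimationError(
            f"no rows remain after exclusions; log: {log.to_list()}"
        )

    z = exposure_mod.compute_exposure(census, df)["exposure_z"].to_numpy()
    y = df[_outcome_column(outcome)].to_numpy(dtype=float)
    x, names = build_covariate_design(df, birth_year_mode=config.birth_year_mode)
    frame = AnalysisFrame(y=y, t=t, z=z, x=x, x_names=names)
    return frame, log


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

@dataclass
class ResultsTable:
    """Per-analysis rows; every second stage travels with its first-stage F."""

    rows: list = field(default_factory=list)
    exclusions: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def add_fit(self, label: str, outcome: str, fit: IVFit) -> None:
        sc = fit.scale
        self.rows.append(
            {
                "label": label,
                "outcome": outcome,
                "outcome_scale": "percentage points" if sc == 100.0 else "PHQ-8 points",
                "n": fit.n,
                "first_stage": fit.pi_first_stage.to_dict(),
                "first_stage_f": fit.f_first_stage,
                "reduced_form": fit.rho_reduced_form.scaled(sc).to_dict(),
                "second_stage": fit.beta_2sls.scaled(sc).to_dict(),
                "ols": fit.beta_ols.scaled(sc).to_dict(),
                "se_type": fit.se_type,
                "weak_instrument": fit.weak_instrument,
                "estimable": True,
            }
        )

    def add_unestimable(self, label: str, outcome: str, n: int, reason: str) -> None:
        self.rows.append(
            {
                "label": label,
                "outcome": outcome,
                "n": n,
                "estimable": False,
                "reason": reason,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        flat = []
        for r in self.rows:
            row = {k: r[k] for k in ("label", "outcome", "n", "estimable")}
            if r["estimable"]:
                row.update(
                    first_stage=r["first_stage"]["estimate"],
                    first_stage_ci_low=r["first_stage"]["ci_low"],
                    first_stage_ci_high=r["first_stage"]["ci_high"],
                    first_stage_f=r["first_stage_f"],
                    second_stage=r["second_stage"]["estimate"],
                    second_stage_ci_low=r["second_stage"]["ci_low"],
                    second_stage_ci_high=r["second_stage"]["ci_high"],
                    ols=r["ols"]["estimate"],
                    ols_ci_low=r["ols"]["ci_low"],
                    ols_ci_high=r["ols"]["ci_high"],
                    outcome_scale=r["outcome_scale"],
                )
            else:
                row["reason"] = r["reason"]
            flat.append(row)
        return pd.DataFrame(flat)

    def format_text(self) -> str:
        lines = []
        header = (
            f"{'analysis':<34}{'outcome':<10}{'n':>8}  "
            f"{'1st stage (95% CI)':>28}{'F':>8}  "
            f"{'2SLS (95% CI)':>28}  {'OLS (95% CI)':>28}"
        )
        lines.append(header)
        lines.append("-" * len(header))
        for r in self.rows:
            if not r["estimable"]:
                lines.append(
                    f"{r['label']:<34}{r['outcome']:<10}{r['n']:>8}  "
                    f"unestimable: {r['reason']}"
                )
                continue

            def fmt(d):
                return f"{d['estimate']:8.3f} ({d['ci_low']:7.3f},{d['ci_high']:7.3f})"

            lines.append(
                f"{r['label']:<34}{r['outcome']:<10}{r['n']:>8}  "
                f"{fmt(r['first_stage']):>28}{r['first_stage_f']:>8.1f}  "
                f"{fmt(r['second_stage']):>28}  {fmt(r['ols']):>28}"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {"settings": self.settings, "exclusions": self.exclusions, "rows": self.rows},
            indent=2,
        )

    def write(self, outdir, stem: str) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{stem}.json").write_text(self.to_json())
        self.to_frame().to_csv(outdir / f"{stem}.csv", index=False)
        (outdir / f"{stem}.txt").write_text(self.format_text() + "\n")


def _fit_row(
    table: ResultsTable,
    label: str,
    census,
    survey,
    config: StudyConfig,
    treatment: str,
    outcome: str,
    coding=None,
    subset=None,
) -> None:
    try:
        frame, log = assemble_frame(
            census, survey, config, treatment=treatment, coding=coding,
            outcome=outcome, subset=subset,
        )
    except (EstimationError, exposure_mod.UnknownCountyError) as err:
        table.add_unestimable(label, outcome, 0, str(err))
        return
    table.exclusions[f"{label}/{outcome}"] = log.to_list()
    try:
        if outcome == "caseness":
            fit = linear_probability_iv(frame, se_type=config.se_type)
        else:
            fit = fit_2sls(frame, se_type=config.se_type)
    except WeakInstrumentError as err:
        table.add_unestimable(
            label, outcome, frame.n, f"weak instrument (F = {err.f_stat:.3g} < 1)"
        )
        return
    except EstimationError as err:
        table.add_unestimable(label, outcome, frame.n, str(err))
        return
    table.add_fit(label, outcome, fit)


def _load_inputs(config: StudyConfig):
    census = exposure_mod.load_census(config.census_path)
    survey = load_survey(config.survey_path)
    return census, survey


def run_main(config: StudyConfig) -> ResultsTable:
    """Main analyses: continuous and dichotomised treatments on both outcomes."""
    census, survey = _load_inputs(config)
    table = ResultsTable(settings=config.settings_dict())
    for treatment, label in (
        ("continuous", f"teeth ({config.coding.name} coded)"),
        ("any_loss", ">=1 tooth lost vs full dentition"),
        ("edentulous", "all teeth lost vs >=1 remaining"),
    ):
        for outcome in ("total", "caseness"):
            _fit_row(table, label, census, survey, config, treatment, outcome)
    return table


def _strata_definitions(survey: pd.DataFrame, config: StudyConfig) -> list:
    age = survey["wave"].to_numpy() - survey["birth_year"].to_numpy()
    defs = [
        (f"age < {config.age_split}", age < config.age_split),
        (f"age >= {config.age_split}", age >= config.age_split),
        (
            f"born <= {config.birth_year_split}",
            survey["birth_year"].to_numpy() <= config.birth_year_split,
        ),
        (
            f"born > {config.birth_year_split}",
            survey["birth_year"].to_numpy() > config.birth_year_split,
        ),
        ("women", (survey["gender"] == "female").to_numpy()),
        ("men", (survey["gender"] == "male").to_numpy()),
    ]
    if "income_stratum" in survey.columns:
        defs += [
            ("income < $50k", (survey["income_stratum"] == "lt50k").to_numpy()),
            ("income >= $50k", (survey["income_stratum"] == "ge50k").to_numpy()),
        ]
    if "dental_visit_stratum" in survey.columns:
        defs += [
            (
                "dental visit within year",
                (survey["dental_visit_stratum"] == "within_year").to_numpy(),
            ),
            (
                "no dental visit within year",
                (survey["dental_visit_stratum"] != "within_year").to_numpy(),
            ),
        ]
    return defs


def run_stratified(config: StudyConfig, outcome: str = "total") -> ResultsTable:
    """Fig.-1-style stratified analyses; strata are fitted independently."""
    census, survey = _load_inputs(config)
    table = ResultsTable(settings=config.settings_dict())
    for label, mask in _strata_definitions(survey, config):
        _fit_row(
            table, label, census, survey, config, "continuous", outcome, subset=mask
        )
    return table


def run_sensitivity(config: StudyConfig, codings=None) -> ResultsTable:
    """Re-run the continuous analyses under alternative bracket codings."""
    census, survey = _load_inputs(config)
    codings = list(codings or config.sensitivity_codings)
    table = ResultsTable(settings=config.settings_dict())
    for coding in [config.coding] + codings:
        for outcome in ("total", "caseness"):
            _fit_row(
                table,
                f"coding {coding.name} {coding.values}",
                census,
                survey,
                config,
                "continuous",
                outcome,
                coding=coding,
            )
    return table


def run_item_level(config: StudyConfig) -> ResultsTable:
    """One 2SLS run per PHQ-8 item score (0-3 outcome), same design."""
    census, survey = _load_inputs(config)
    table = ResultsTable(settings=config.settings_dict())
    for j in range(1, phq8.N_ITEMS + 1):
        outcome = f"item{j}"
        try:
            frame, log = assemble_frame(
                census, survey, config, treatment="continuous", outcome=outcome
            )
        except EstimationError as err:
            table.add_unestimable(f"PHQ item {j}", outcome, 0, str(err))
            continue
        if np.var(frame.y) == 0:
            table.add_unestimable(
                f"PHQ item {j}", outcome, frame.n, "outcome has no variation"
            )
            continue
        table.exclusions[f"item{j}"] = log.to_list()
        try:
            table.add_fit(f"PHQ item {j}", outcome, fit_2sls(frame, se_type=config.se_type))
        except (WeakInstrumentError, EstimationError) as err:
            table.add_unestimable(f"PHQ item {j}", outcome, frame.n, str(err))
    return table
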