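"""Synthetic BRFSS-style population with a staggered fluoridation rollout.

Emulates the study design end-to-end with a KNOWN truth so the whole pipeline
is testable without restricted survey microdata:

* a fluoridation census — counties adopt fluoridation in staggered years with
  county-specific coverage (a fraction never adopt), giving historical and
  geographical variation in childhood exposure;
* respondents with birth cohort, survey wave, gender, state and county, whose
  childhood exposure Z is computed by the same accumulation rule the analysis
  uses (ages 5-14, rescaled to [0, 1]);
* a structural model with an unobserved standard-normal confounder U acting on
  both tooth loss and depression — exactly the omitted-variable problem the
  instrumental-variable design exists to defeat:

      T* = base + pi*Z + gamma_T*U + covariates + noise,  clamped to 0-28
      bracket = BRFSS bracket of T*;  c = midpoint coding of the bracket
      D  = alpha + beta*c + gamma_Y*U + covariates + noise   (latent, 0-24 scale)

  The depression equation carries beta on the midpoint-coded count c — the
  scale the analyst's regressions use — so the 2SLS estimand equals beta
  exactly and the OLS omitted-variable bias has the closed form
  gamma_Y * cov(c~, U) / var(c~) (tildes denote residuals on the covariates).

* PHQ-8 item day-counts drawn Binomial(14, p_i) with logistic links in the
  latent D, after passing D through the inverse of the expected-total curve
  S(d) = E[scored total | d]; this calibration makes E[PHQ-8 total | D] = D on
  the interior of (0, 24), so scoring is monotone, integer-valued, noisy — and
  mean-unbiased, which is what makes exact recovery of beta possible.

A TruthRecord (true beta, first-stage pi, the analytic OLS bias) is emitted
beside every dataset for recovery tests; the estimation modules never read it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binom

from . import coding as coding_mod
from . import exposure as exposure_mod
from . import phq8
from .iv import build_covariate_design

WAVES = (2006, 2008, 2010)
MAX_TEETH = 28
_MOMENT_SEED = 190401  # fixed stream for analytic-bias plug-in moments
_MOMENT_N = 200_000


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CovariateEffects:
    """Structural shifts of observed covariates on teeth (T) and depression (Y).

    Units: teeth (T column) and PHQ-8 points (Y column). Birth-year effects are
    per year relative to the cohort midpoint; state effects are the SD of
    state-level normal shifts (drawn once per state from a dedicated stream).
    """

    gender_t: float = 0.8  # men report slightly more lost teeth
    gender_y: float = -0.4  # men report fewer depressive symptoms
    birth_year_t: float = -0.12  # younger cohorts keep more teeth
    birth_year_y: float = 0.02
    state_sd_t: float = 0.5
    state_sd_y: float = 0.3


@dataclass(frozen=True)
class GeneratorConfig:
    n_counties: int = 250
    n_respondents: int = 20_000
    birth_year_range: tuple[int, int] = (1940, 1978)
    rollout_year_range: tuple[int, int] = (1945, 1992)
    # coverage at adoption ~ Beta(alpha, beta); a fraction of counties never adopt
    coverage_alpha: float = 4.0
    coverage_beta: float = 2.0
    prop_never_adopt: float = 0.25
    trajectory: str = "constant"  # or "ramp" (linear ramp-up over ramp_years)
    ramp_years: int = 10
    # structural parameters
    true_beta: float = 0.15  # PHQ-8 points per coded lost tooth
    gender_beta_shift: float = 0.0  # optional effect heterogeneity (added for men)
    first_stage_pi: float = -0.56  # latent teeth per unit instrument (<= 0)
    confounder_gamma_t: float = 2.0  # teeth per unit confounder
    confounder_gamma_y: float = 0.5  # PHQ points per unit confounder
    base_teeth: float = 0.0  # latent tooth-count intercept at the cohort midpoint
    # complete edentulism is a distinct clinical endpoint (full-mouth
    # extraction), not the tail of the count distribution: probability
    # expit((latent - threshold)/scale) of losing all 28 teeth
    edentulous_threshold: float = 20.0
    edentulous_scale: float = 4.0
    alpha_y: float = 2.3  # latent depression intercept
    covariate_effects: CovariateEffects = CovariateEffects()
    noise_sd_t: float = 6.0
    noise_sd_latent_y: float = 4.0
    # survey composition
    n_states: int = 12
    prop_male: float = 0.387
    # PHQ item links: p_i(d) = expit((d - offset_i) / scale)
    item_offsets: tuple[float, ...] = (6.0, 7.5, 9.0, 10.5, 12.0, 13.5, 15.0, 16.5)
    item_scale: float = 4.0
    item_loadings: tuple[float, ...] = (1.0,) * 8  # treatment loading per item
    seed: int = 0

    def __post_init__(self):
        if self.n_counties <= 0 or self.n_respondents <= 0:
            raise GeneratorConfigError("n_counties and n_respondents must be positive")
        for name in ("birth_year_range", "rollout_year_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise GeneratorConfigError(f"{name} must be an increasing pair")
        for name in ("prop_never_adopt", "prop_male"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise GeneratorConfigError(f"{name} must lie in [0, 1]")
        for name in ("noise_sd_t", "noise_sd_latent_y", "item_scale"):
            if getattr(self, name) <= 0:
                raise GeneratorConfigError(f"{name} must be positive")
        if self.coverage_alpha <= 0 or self.coverage_beta <= 0:
            raise GeneratorConfigError("coverage Beta parameters must be positive")
        if self.first_stage_pi > 0:
            raise GeneratorConfigError(
                "first_stage_pi must be <= 0 (fluoridation prevents tooth loss)"
            )
        if self.trajectory not in ("constant", "ramp"):
            raise GeneratorConfigError("trajectory must be 'constant' or 'ramp'")
        if len(self.item_offsets) != phq8.N_ITEMS or len(self.item_loadings) != phq8.N_ITEMS:
            raise GeneratorConfigError("item_offsets/item_loadings need 8 entries")
        if any(w < 0 for w in self.item_loadings):
            raise GeneratorConfigError("item loadings must be non-negative")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TruthRecord:
    """Data-generating truth stored beside every synthetic dataset.

    ``ols_bias_expected`` is the omitted-variable bias
    gamma_Y * cov(c~, U) / var(c~) evaluated by plug-in on a large auxiliary
    draw (bracket discretisation leaves no fully closed-form moment); it is the
    expected gap between the naive OLS slope and the true causal effect.
    Never consumed by the estimation modules.
    """

    true_beta: float
    first_stage_pi: float
    ols_bias_expected: float
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def generate_census(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a per-county, per-year fluoridation table over the rollout span."""
    rng = _rng(config, 0)
    y0, y1 = config.rollout_year_range
    years = np.arange(y0, y1 + 1)
    county_ids = np.array([f"C{i:04d}" for i in range(config.n_counties)])

    never = rng.random(config.n_counties) < config.prop_never_adopt
    adopt_year = rng.integers(y0, y1 + 1, size=config.n_counties)
    coverage = rng.beta(config.coverage_alpha, config.coverage_beta, config.n_counties)

    grid = np.zeros((config.n_counties, years.size))
    since = years[None, :] - adopt_year[:, None]  # years since adoption
    if config.trajectory == "constant":
        frac = (since >= 0).astype(float)
    else:  # linear ramp to full coverage over ramp_years
        frac = np.clip((since + 1) / config.ramp_years, 0.0, 1.0)
        frac[since < 0] = 0.0
    grid = coverage[:, None] * frac
    grid[never] = 0.0

    return pd.DataFrame(
        {
            "county_id": np.repeat(county_ids, years.size),
            "year": np.tile(years, config.n_counties),
            "proportion_fluoridated": grid.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# PHQ item link calibration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _score_link(item_offsets: tuple, item_scale: float, upper_bounds: tuple):
    """Grid of the expected-total curve S(d) and its inverse.

    S(d) = sum_i E[score(Binomial(14, p_i(d)))] is strictly increasing from 0
    to 24; returns (d_grid, s_grid) for interpolation in both directions.
    """
    d_grid = np.linspace(-60.0, 90.0, 3001)
    scores = np.asarray(
        [np.searchsorted(np.asarray(upper_bounds), k) for k in range(phq8.MAX_DAYS + 1)]
    )
    s_grid = np.zeros_like(d_grid)
    for a in item_offsets:
        p = expit((d_grid - a) / item_scale)
        pmf = binom.pmf(np.arange(phq8.MAX_DAYS + 1)[None, :], phq8.MAX_DAYS, p[:, None])
        s_grid += pmf @ scores
    return d_grid, s_grid


def _latent_to_adjusted(latent: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Invert the expected-total curve: find d with S(d) = latent."""
    d_grid, s_grid = _score_link(
        config.item_offsets, config.item_scale, phq8.DEFAULT_MAPPING.upper_bounds
    )
    eps = 1e-6
    clipped = np.clip(latent, s_grid[0] + eps, s_grid[-1] - eps)
    return np.interp(clipped, s_grid, d_grid)


# ---------------------------------------------------------------------------
# structural draw (shared by the main generator and the moment plug-in)
# ---------------------------------------------------------------------------

def _draw_structural(
    config: GeneratorConfig, census: pd.DataFrame, rng: np.random.Generator, n: int
) -> dict:
    county_ids = np.sort(census["county_id"].unique())
    if county_ids.size != config.n_counties:
        raise GeneratorConfigError(
            f"census has {county_ids.size} counties but config expects "
            f"{config.n_counties}"
        )
    county_idx = rng.integers(0, config.n_counties, size=n)
    state_idx = county_idx % config.n_states
    b0, b1 = config.birth_year_range
    birth_year = rng.integers(b0, b1 + 1, size=n)
    wave = np.asarray(WAVES)[rng.integers(0, len(WAVES), size=n)]
    is_male = rng.random(n) < config.prop_male

    resp = pd.DataFrame(
        {
            "respondent_id": np.arange(n),
            "birth_year": birth_year,
            "county_id": county_ids[county_idx],
        }
    )
    z = exposure_mod.compute_exposure(census, resp)["exposure_z"].to_numpy()

    # state-level structural shifts: fixed per config, not per sample size
    state_rng = _rng(config, 33)
    eff = config.covariate_effects
    state_t = state_rng.normal(0.0, eff.state_sd_t, config.n_states)
    state_y = state_rng.normal(0.0, eff.state_sd_y, config.n_states)

    mid = 0.5 * (b0 + b1)
    cov_t = (
        eff.gender_t * is_male
        + eff.birth_year_t * (birth_year - mid)
        + state_t[state_idx]
    )
    cov_y = (
        eff.gender_y * is_male
        + eff.birth_year_y * (birth_year - mid)
        + state_y[state_idx]
    )

    u = rng.normal(0.0, 1.0, n)
    latent_t = (
        config.base_teeth
        + config.first_stage_pi * z
        + config.confounder_gamma_t * u
        + cov_t
        + rng.normal(0.0, config.noise_sd_t, n)
    )
    t_int = np.clip(np.rint(latent_t), 0, MAX_TEETH).astype(int)
    p_edent = expit((latent_t - config.edentulous_threshold) / config.edentulous_scale)
    t_int[rng.random(n) < p_edent] = MAX_TEETH
    bracket = coding_mod.bracket_from_count(t_int)
    coded = coding_mod.code_continuous(bracket)

    return {
        "county_idx": county_idx,
        "county_id": county_ids[county_idx],
        "state": np.array([f"S{i:02d}" for i in range(config.n_states)])[state_idx],
        "birth_year": birth_year,
        "wave": wave,
        "is_male": is_male,
        "z": z,
        "u": u,
        "t_int": t_int,
        "bracket": bracket,
        "coded": coded,
        "cov_y": cov_y,
    }


def _covariate_frame(s: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "birth_year": s["birth_year"],
            "wave": s["wave"],
            "gender": np.where(s["is_male"], "male", "female"),
            "state": s["state"],
        }
    )


# ---------------------------------------------------------------------------
# analytic OLS bias (plug-in moments) and confounding calibration
# ---------------------------------------------------------------------------

def _bias_moments(config: GeneratorConfig, n: int = _MOMENT_N) -> float:
    """cov(c~, U)/var(c~) with c, U residualised on the covariate design."""
    census = generate_census(config)
    rng = _rng(config, 44)
    s = _draw_structural(config, census, rng, n)
    x, _ = build_covariate_design(_covariate_frame(s))
    coefs, *_ = np.linalg.lstsq(x, np.column_stack([s["coded"], s["u"]]), rcond=None)
    resid = np.column_stack([s["coded"], s["u"]]) - x @ coefs
    c_res, u_res = resid[:, 0], resid[:, 1]
    return float(c_res @ u_res / (c_res @ c_res))


@lru_cache(maxsize=64)
def _bias_slope_cached(config: GeneratorConfig) -> float:
    # population moment: average the plug-in over several independent census
    # realisations and draws (the slope varies ~1% across censuses); seed and
    # sample size of the passed config are irrelevant to the value
    slopes = [
        _bias_moments(config.replace(seed=_MOMENT_SEED + k, n_respondents=1))
        for k in range(6)
    ]
    return float(np.mean(slopes))


def _slope_key(config: GeneratorConfig) -> GeneratorConfig:
    # the slope is invariant to seed and sample size; normalise the cache key
    return config.replace(seed=_MOMENT_SEED, n_respondents=1)


def expected_ols_bias(config: GeneratorConfig) -> float:
    """Analytic omitted-variable bias gamma_Y * cov(c~, U)/var(c~) for a config."""
    return config.confounder_gamma_y * _bias_slope_cached(_slope_key(config))


def calibrate_confounding(config: GeneratorConfig, target_bias: float) -> GeneratorConfig:
    """Set gamma_Y so the analytic OLS bias equals ``target_bias``."""
    slope = _bias_slope_cached(_slope_key(config))
    # below the Monte-Carlo resolution of the plug-in moments the confounding
    # direction is not identified
    if abs(slope) < 1e-3:
        raise GeneratorConfigError(
            "confounder does not move the coded treatment (gamma_T ~ 0); "
            "cannot calibrate the outcome confounding"
        )
    return config.replace(confounder_gamma_y=target_bias / slope)


# ---------------------------------------------------------------------------
# respondents
# ---------------------------------------------------------------------------

def generate_respondents(
    config: GeneratorConfig, census: pd.DataFrame, return_latent: bool = False
):
    """Draw the survey table (and TruthRecord) from a fluoridation census.

    Returns ``(survey, truth)`` or ``(survey, truth, latent)`` when
    ``return_latent`` is set; the latent frame (confounder U, integer tooth
    count, latent depression) exists for diagnostics and tests only.
    """
    rng = _rng(config, 1)
    s = _draw_structural(config, census, rng, config.n_respondents)

    beta_i = config.true_beta + config.gender_beta_shift * s["is_male"]
    base_latent = (
        config.alpha_y
        + config.confounder_gamma_y * s["u"]
        + s["cov_y"]
        + rng.normal(0.0, config.noise_sd_latent_y, config.n_respondents)
    )
    loadings = np.asarray(config.item_loadings)
    # per-item latent: shared base plus the item's treatment loading
    latent_items = base_latent[:, None] + loadings[None, :] * (beta_i * s["coded"])[:, None]
    d_adj = _latent_to_adjusted(latent_items, config)
    probs = expit((d_adj - np.asarray(config.item_offsets)[None, :]) / config.item_scale)
    days = rng.binomial(phq8.MAX_DAYS, probs)

    survey = pd.DataFrame(
        {
            "respondent_id": np.arange(config.n_respondents),
            "birth_year": s["birth_year"],
            "wave": s["wave"],
            "gender": np.where(s["is_male"], "male", "female"),
            "state": s["state"],
            "county_id": s["county_id"],
            "teeth_bracket": s["bracket"],
        }
    )
    for j, col in enumerate(phq8.ITEM_COLUMNS):
        survey[col] = days[:, j]
    strata_rng = _rng(config, 2)
    survey["income_stratum"] = np.where(
        strata_rng.random(config.n_respondents) < 0.5, "lt50k", "ge50k"
    )
    survey["dental_visit_stratum"] = np.where(
        strata_rng.random(config.n_respondents) < 0.5, "within_year", "over_year"
    )

    truth = TruthRecord(
        true_beta=config.true_beta,
        first_stage_pi=config.first_stage_pi,
        ols_bias_expected=expected_ols_bias(config),
        seed=config.seed,
    )
    if not return_latent:
        return survey, truth
    latent = pd.DataFrame(
        {
            "u": s["u"],
            "exposure_z": s["z"],
            "tooth_count": s["t_int"],
            "coded_teeth": s["coded"],
            "latent_depression": base_latent + beta_i * s["coded"],
        }
    )
    return survey, truth, latent


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Survey-scale preset: realistic skewed depression scores, mean coded
    tooth loss near 4.5, and a first-stage slope on the order the fluoridation
    literature reports (about half a tooth per full childhood exposure)."""
    return GeneratorConfig(seed=seed, **overrides)


def recovery_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Strong-instrument preset for parameter-recovery and coverage studies.

    The latent depression score is centred mid-scale (so score clamping at 0
    and 24 cannot attenuate slopes), the first stage is strong enough that
    just-identified 2SLS is in its asymptotic regime at n of a few thousand,
    and the outcome confounding is calibrated so the analytic OLS
    omitted-variable bias equals +0.05 PHQ points per tooth.
    """
    params = dict(
        seed=seed,
        n_counties=200,
        n_respondents=5_000,
        first_stage_pi=-3.0,
        confounder_gamma_t=1.5,
        noise_sd_t=3.0,
        base_teeth=3.5,
        alpha_y=12.0,
        noise_sd_latent_y=2.5,
        covariate_effects=CovariateEffects(
            gender_t=0.8,
            gender_y=-0.4,
            birth_year_t=-0.05,
            birth_year_y=0.02,
            state_sd_t=0.3,
            state_sd_y=0.2,
        ),
    )
    params.update(overrides)
    return calibrate_confounding(GeneratorConfig(**params), target_bias=0.05)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_dataset(config: GeneratorConfig, outdir) -> dict:
    """Generate and write census CSV, survey CSV and truth JSON; returns paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    census = generate_census(config)
    survey, truth = generate_respondents(config, census)
    paths = {
        "census": outdir / "fluoridation_census.csv",
        "survey": outdir / "survey.csv",
        "truth": outdir / "truth.json",
    }
    census.to_csv(paths["census"], index=False)
    survey.to_csv(paths["survey"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
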