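"""Linear estimation core: OLS, first stage, reduced form, and 2SLS.

All estimators are just-identified instrumental-variable regressions with a
single excluded instrument Z, a scalar treatment T, and an exogenous covariate
design X (which must include the intercept):

    first stage:   T = Z*pi  + X*delta + v
    reduced form:  Y = Z*rho + X*phi   + w
    second stage:  Y = That*beta + X*gamma + e,  That = first-stage fitted T

The 2SLS covariance uses STRUCTURAL residuals Y - T*beta - X*gamma (actual T,
not That). With one instrument the estimator satisfies the Wald identity
beta = rho / pi exactly, and the first-stage F equals the squared t-statistic
of Z. Standard errors are heteroskedasticity-robust (HC1) by default, with
classical and cluster-robust (CR1) variants available. Confidence intervals
are the normal approximation estimate +/- 1.96*SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg

Z_CRIT = 1.96  # normal-approximation 95% interval
WEAK_F_REFUSE = 1.0  # below this first-stage F the 2SLS estimate is withheld
WEAK_F_WARN = 10.0  # conventional weak-instrument bar

SE_TYPES = ("robust", "classical", "cluster")


class EstimationError(ValueError):
    pass


class SingularDesignError(EstimationError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class DegenerateInstrumentError(EstimationError):
    """Instrument (or its residual after the covariates) has no variance."""


class UnsupportedConfigurationError(EstimationError):
    """Raised for over-identified configurations (more than one instrument)."""


class WeakInstrumentError(EstimationError):
    """First-stage F below the refusal tolerance; carries the F value."""

    def __init__(self, f_stat: float):
        self.f_stat = float(f_stat)
        super().__init__(
            f"first-stage F = {f_stat:.4g} < {WEAK_F_REFUSE}: instrument too weak "
            "to report a 2SLS estimate"
        )


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass(frozen=True)
class AnalysisFrame:
    """Assembled estimation table.

    ``x`` must contain the intercept and the covariate contrast columns
    (reference categories already dropped); ``x_names`` labels them.
    """

    y: np.ndarray
    t: np.ndarray
    z: np.ndarray
    x: np.ndarray
    x_names: tuple[str, ...] = ()

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        t = np.asarray(self.t, dtype=float)
        z = np.asarray(self.z, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if z.ndim == 2:
            if z.shape[1] != 1:
                raise UnsupportedConfigurationError(
                    "only one excluded instrument is supported (just-identified 2SLS)"
                )
            z = z[:, 0]
        if x.ndim != 2:
            raise EstimationError("covariate design must be 2-D")
        n = y.shape[0]
        if not (t.shape[0] == z.shape[0] == x.shape[0] == n):
            raise EstimationError("y, t, z, x must have equal row counts")
        for name, arr in (("y", y), ("t", t), ("z", z), ("x", x)):
            if np.isnan(arr).any():
                raise EstimationError(f"missing values in {name}; frames are complete-case")
        names = self.x_names or tuple(f"x{j}" for j in range(x.shape[1]))
        if len(names) != x.shape[1]:
            raise EstimationError("x_names length does not match design width")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "x_names", tuple(names))

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass(frozen=True)
class Estimate:
    """Coefficient with standard error and 95% normal-approximation CI."""

    value: float
    se: float

    @property
    def ci_low(self) -> float:
        return self.value - Z_CRIT * self.se

    @property
    def ci_high(self) -> float:
        return self.value + Z_CRIT * self.se

    def scaled(self, factor: float) -> "Estimate":
        return Estimate(self.value * factor, self.se * factor)

    def to_dict(self) -> dict:
        return {
            "estimate": self.value,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass(frozen=True)
class IVFit:
    """Full fit report for one analysis frame."""

    beta_2sls: Estimate
    pi_first_stage: Estimate
    rho_reduced_form: Estimate
    beta_ols: Estimate
    f_first_stage: float
    n: int
    se_type: str
    weak_instrument: bool  # True when F below the conventional bar of 10
    scale: float = 1.0  # reporting multiplier (100 for percentage points)

    def to_dict(self) -> dict:
        d = {
            "beta_2sls": self.beta_2sls.scaled(self.scale).to_dict(),
            "pi_first_stage": self.pi_first_stage.to_dict(),
            "rho_reduced_form": self.rho_reduced_form.scaled(self.scale).to_dict(),
            "beta_ols": self.beta_ols.scaled(self.scale).to_dict(),
            "f_first_stage": self.f_first_stage,
            "n": self.n,
            "se_type": self.se_type,
            "weak_instrument": self.weak_instrument,
            "scale": self.scale,
        }
        return d


DEFAULT_FACTORS = ("birth_year", "wave", "gender", "state")


def build_covariate_design(
    df: pd.DataFrame,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    birth_year_mode: str = "indicators",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Build the exogenous covariate design (intercept + contrast columns).

    Each factor becomes indicator columns with the lexicographically first
    level dropped as reference (deterministic across runs). ``birth_year`` can
    instead enter as a single centred linear trend (``birth_year_mode=
    'linear'``), the alternative reading of "adjusting for year of birth".
    """
    if birth_year_mode not in ("indicators", "linear"):
        raise EstimationError("birth_year_mode must be 'indicators' or 'linear'")
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for factor in factors:
        if factor not in df.columns:
            raise EstimationError(f"covariate column missing from table: {factor!r}")
        if factor == "birth_year" and birth_year_mode == "linear":
            by = df[factor].to_numpy(dtype=float)
            cols.append(by - by.mean())
            names.append("birth_year_linear")
            continue
        levels = sorted(df[factor].astype(str).unique())
        vals = df[factor].astype(str).to_numpy()
        for level in levels[1:]:  # drop lexicographically first level
            cols.append((vals == level).astype(float))
            names.append(f"{factor}[{level}]")
    return np.column_stack(cols), tuple(names)


def _check_se_type(se_type: str, clusters) -> None:
    if se_type not in SE_TYPES:
        raise EstimationError(f"se_type must be one of {SE_TYPES}, got {se_type!r}")
    if se_type == "cluster" and clusters is None:
        raise EstimationError("cluster se_type requires a cluster id per row")


def _solve_full_rank(w: np.ndarray, names) -> tuple[np.ndarray, np.ndarray]:
    """QR-factorise the design; raise SingularDesignError naming bad columns."""
    q, r, piv = scipy.linalg.qr(w, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(w.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < w.shape[1]:
        collinear = [names[j] for j in sorted(piv[rank:])]
        raise SingularDesignError(collinear)
    return q, r[:, np.argsort(piv)]  # undo pivoting so R maps original order


def _coef_and_cov(
    w: np.ndarray,
    y: np.ndarray,
    names,
    se_type: str,
    clusters=None,
    resid_override: Optional[np.ndarray] = None,
):
    """Least-squares coefficients of y on w, with the requested covariance.

    ``resid_override`` substitutes structural residuals in the meat/scale of
    the covariance (the 2SLS case) while the bread stays (w'w)^-1.
    """
    n, k = w.shape
    if n <= k:
        raise EstimationError(f"need n > k, got n={n}, k={k}")
    q, _ = _solve_full_rank(w, names)
    # solve via the unpivoted normal equations in QR form
    coef, *_ = np.linalg.lstsq(w, y, rcond=None)
    resid = y - w @ coef
    e = resid if resid_override is None else resid_override

    wtw_inv = np.linalg.inv(w.T @ w)
    if se_type == "classical":
        sigma2 = float(e @ e) / (n - k)
        cov = sigma2 * wtw_inv
    elif se_type == "robust":  # HC1
        meat = (w * (e**2)[:, None]).T @ w
        cov = wtw_inv @ meat @ wtw_inv * (n / (n - k))
    else:  # CR1 cluster-robust
        cl = np.asarray(clusters)
        labels, inv = np.unique(cl, return_inverse=True)
        g = labels.shape[0]
        we = w * e[:, None]
        sums = np.zeros((g, k))
        np.add.at(sums, inv, we)
        meat = sums.T @ sums
        correction = (g / (g - 1)) * ((n - 1) / (n - k)) if g > 1 else 1.0
        cov = wtw_inv @ meat @ wtw_inv * correction
    return coef, cov, resid


def _lead_estimate(coef, cov) -> Estimate:
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    return Estimate(float(coef[0]), se)


def fit_ols(frame: AnalysisFrame, se_type: str = "robust", clusters=None) -> Estimate:
    """OLS of Y on (T, X); returns T's coefficient."""
    _check_se_type(se_type, clusters)
    w = np.column_stack([frame.t, frame.x])
    names = ("treatment",) + frame.x_names
    coef, cov, _ = _coef_and_cov(w, frame.y, names, se_type, clusters)
    return _lead_estimate(coef, cov)


def fit_first_stage(
    frame: AnalysisFrame, se_type: str = "robust", clusters=None
) -> tuple[Estimate, float]:
    """Regress T on (Z, X); returns Z's coefficient and the excluded-instrument F.

    With a single instrument F = (pi_hat / SE(pi_hat))^2 under the selected
    covariance estimator.
    """
    _check_se_type(se_type, clusters)
    if np.ptp(frame.z) == 0:
        raise DegenerateInstrumentError("instrument has zero variance")
    w = np.column_stack([frame.z, frame.x])
    names = ("instrument",) + frame.x_names
    coef, cov, _ = _coef_and_cov(w, frame.t, names, se_type, clusters)
    est = _lead_estimate(coef, cov)
    if est.se == 0:
        f = np.inf
    else:
        f = (est.value / est.se) ** 2
    return est, float(f)


def fit_reduced_form(
    frame: AnalysisFrame, se_type: str = "robust", clusters=None
) -> Estimate:
    """Regress Y on (Z, X); returns Z's coefficient."""
    _check_se_type(se_type, clusters)
    if np.ptp(frame.z) == 0:
        raise DegenerateInstrumentError("instrument has zero variance")
    w = np.column_stack([frame.z, frame.x])
    names = ("instrument",) + frame.x_names
    coef, cov, _ = _coef_and_cov(w, frame.y, names, se_type, clusters)
    return _lead_estimate(coef, cov)


def fit_2sls(
    frame: AnalysisFrame,
    se_type: str = "robust",
    clusters=None,
    scale: float = 1.0,
) -> IVFit:
    """Two-stage least squares with structural-residual covariance.

    Raises WeakInstrumentError when the first-stage F falls below 1; sets the
    ``weak_instrument`` flag (and emits a WeakInstrumentWarning) when F < 10.
    """
    _check_se_type(se_type, clusters)
    pi, f_stat = fit_first_stage(frame, se_type, clusters)
    rho = fit_reduced_form(frame, se_type, clusters)
    ols = fit_ols(frame, se_type, clusters)

    if f_stat < WEAK_F_REFUSE:
        raise WeakInstrumentError(f_stat)
    weak = f_stat < WEAK_F_WARN
    if weak:
        warnings.warn(
            f"first-stage F = {f_stat:.3g} < {WEAK_F_WARN}: weak instrument, "
            "2SLS estimate may be unreliable",
            WeakInstrumentWarning,
            stacklevel=2,
        )

    # first-stage fitted values
    wz = np.column_stack([frame.z, frame.x])
    fs_coef, *_ = np.linalg.lstsq(wz, frame.t, rcond=None)
    t_hat = wz @ fs_coef

    w2 = np.column_stack([t_hat, frame.x])
    names = ("treatment_hat",) + frame.x_names
    coef2, *_ = np.linalg.lstsq(w2, frame.y, rcond=None)
    # structural residuals use the ACTUAL treatment
    w_actual = np.column_stack([frame.t, frame.x])
    structural_resid = frame.y - w_actual @ coef2
    _, cov2, _ = _coef_and_cov(
        w2, frame.y, names, se_type, clusters, resid_override=structural_resid
    )
    beta = _lead_estimate(coef2, cov2)

    fit = IVFit(
        beta_2sls=beta,
        pi_first_stage=pi,
        rho_reduced_form=rho,
        beta_ols=ols,
        f_first_stage=f_stat,
        n=frame.n,
        se_type=se_type,
        weak_instrument=weak,
        scale=scale,
    )
    _check_wald_identity(fit)
    return fit


def _check_wald_identity(fit: IVFit, rtol: float = 1e-8) -> None:
    lhs = fit.beta_2sls.value * fit.pi_first_stage.value
    rhs = fit.rho_reduced_form.value
    denom = max(abs(rhs), abs(lhs), 1e-300)
    if abs(lhs - rhs) / denom > rtol:
        raise EstimationError(
            f"Wald identity violated: beta*pi={lhs!r} vs rho={rhs!r} "
            "(numerical failure in the estimation core)"
        )


def linear_probability_iv(
    frame: AnalysisFrame, se_type: str = "robust", clusters=None
) -> IVFit:
    """2SLS on a binary outcome, reported in percentage points.

    The estimator is identical to :func:`fit_2sls`; only the reporting scale
    changes (coefficients, SEs and CIs multiplied by 100).
    """
    uniq = np.unique(frame.y)
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise EstimationError(
            f"linear probability model requires a 0/1 outcome; found values {uniq[:5]}"
        )
    return fit_2sls(frame, se_type, clusters, scale=100.0)
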