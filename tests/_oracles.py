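"""Independent brute-force oracles for the estimation core.

Deliberately naive implementations: dense normal equations solved directly,
and the Frisch-Waugh-Lovell residual ratio for just-identified IV. These
never share code with the package's estimators.
"""

import numpy as np

from fluoriv.iv import AnalysisFrame


def normal_equations(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(w.T @ w, w.T @ y)


def residualize(v: np.ndarray, x: np.ndarray) -> np.ndarray:
    return v - x @ normal_equations(x, v)


def oracle_ols(frame: AnalysisFrame) -> float:
    w = np.column_stack([frame.t, frame.x])
    return float(normal_equations(w, frame.y)[0])


def oracle_first_stage(frame: AnalysisFrame) -> float:
    w = np.column_stack([frame.z, frame.x])
    return float(normal_equations(w, frame.t)[0])


def oracle_reduced_form(frame: AnalysisFrame) -> float:
    w = np.column_stack([frame.z, frame.x])
    return float(normal_equations(w, frame.y)[0])


def oracle_2sls_fwl(frame: AnalysisFrame) -> float:
    """2SLS as the FWL ratio cov(z~, y~)/cov(z~, t~) after partialling X."""
    zt = residualize(frame.z, frame.x)
    yt = residualize(frame.y, frame.x)
    tt = residualize(frame.t, frame.x)
    return float((zt @ yt) / (zt @ tt))


def random_frame(rng: np.random.Generator, n: int | None = None) -> AnalysisFrame:
    """Random well-conditioned frame with a strong first stage."""
    if n is None:
        n = int(rng.integers(60, 1001))
    k = int(rng.integers(1, 4))
    x = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
    # include a binary covariate like the real design
    x = np.column_stack([x, (rng.random(n) < 0.4).astype(float)])
    names = ("intercept",) + tuple(f"c{j}" for j in range(k)) + ("d0",)
    gx = rng.normal(size=x.shape[1])
    z = rng.uniform(0, 1, n) + 0.3 * (x @ gx)
    pi = rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 2.5)
    t = pi * z + x @ rng.normal(size=x.shape[1]) + rng.normal(size=n)
    beta = rng.uniform(-2, 2)
    y = beta * t + x @ rng.normal(size=x.shape[1]) + rng.normal(size=n)
    return AnalysisFrame(y=y, t=t, z=z, x=x, x_names=names)
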