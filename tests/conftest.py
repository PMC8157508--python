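import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fluoriv as f
from fluoriv.iv import AnalysisFrame
from fluoriv.pipeline import StudyConfig

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def hand_frame() -> AnalysisFrame:
    """Six-row frame whose coefficients were worked out by normal equations
    on paper: OLS 5/4, first stage 3/2, reduced form 2, 2SLS 4/3."""
    return AnalysisFrame(
        y=np.array([2.0, 1, 4, 3, 7, 6]),
        t=np.array([0.0, 1, 2, 3, 4, 5]),
        z=np.array([0.0, 1, 1, 0, 2, 2]),
        x=np.column_stack([np.ones(6), np.array([1.0, 0, 1, 0, 1, 0])]),
        x_names=("intercept", "x1"),
    )


@pytest.fixture(scope="session")
def small_default():
    """Survey-scale synthetic dataset (paper-like regime, modest n)."""
    cfg = f.default_config(seed=7, n_respondents=4000, n_counties=80)
    census = f.generate_census(cfg)
    survey, truth, latent = f.generate_respondents(cfg, census, return_latent=True)
    return cfg, census, survey, truth, latent


@pytest.fixture(scope="session")
def recovery_dataset():
    """Strong-instrument synthetic dataset for estimation-quality tests."""
    cfg = f.recovery_config(seed=11, n_respondents=6000)
    census = f.generate_census(cfg)
    survey, truth, latent = f.generate_respondents(cfg, census, return_latent=True)
    return cfg, census, survey, truth, latent


@pytest.fixture(scope="session")
def recovery_files(tmp_path_factory, recovery_dataset):
    """Recovery dataset written to disk, plus a ready StudyConfig."""
    cfg, census, survey, truth, latent = recovery_dataset
    outdir = tmp_path_factory.mktemp("recovery_data")
    census_path = outdir / "census.csv"
    survey_path = outdir / "survey.csv"
    census.to_csv(census_path, index=False)
    survey.to_csv(survey_path, index=False)
    study = StudyConfig(census_path=str(census_path), survey_path=str(survey_path))
    return study, cfg, truth
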