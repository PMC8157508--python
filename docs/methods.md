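# Methods

## Identification strategy

The package estimates the causal effect of adult tooth loss on depressive
symptoms by instrumental variables. The instrument is cumulative childhood
exposure to community water fluoridation:

    Z_i = (1/10) * sum_{a=5}^{14} p(county_i, birth_year_i + a)

where `p(c, y)` is the proportion of county `c`'s population supplied
fluoridated water in calendar year `y`. The 5–14 age window corresponds to
post-eruptive enamel maturation of the permanent teeth, when fluoride
protection is largest; dividing by 10 bounds `Z` in [0, 1] so coefficients
contrast full vs no childhood exposure. Calendar years before the first
census year contribute 0 (pre-fluoridation era); years after the last census
year carry the county's final observed proportion forward; a county-year
absent from an otherwise-covered census is treated as proportion 0 with a
logged warning, since fluoridation censuses list served populations and
absence means no supply.

Identification rests on (i) relevance — fluoridation prevents caries and
hence tooth loss, checked by the first-stage F; (ii) exclusion — childhood
water fluoride affects adult depression only through dental health; and
(iii) quasi-random assignment of rollout timing conditional on the
covariates (year of birth, survey wave, gender, state). The estimate is a
local average treatment effect: the effect among people whose tooth
retention was actually changed by fluoridation.

## Estimator

All regressions share an exogenous design X: intercept, year-of-birth
indicators (default; a linear-trend option exists because "adjusting for
year of birth" admits both readings), survey-wave indicators, a gender
indicator and state indicators, each dropping the lexicographically first
level for determinism. With a single excluded instrument the model is
just-identified, so

    beta_2SLS = rho / pi        (Wald identity, checked on every fit)

where `pi` and `rho` are the first-stage and reduced-form coefficients of Z.
The second stage regresses Y on the first-stage fitted treatment and X, but
its covariance is computed from structural residuals `Y - T*beta - X*gamma`
with the *actual* treatment — using second-stage residuals would understate
the variance. Standard errors default to HC1 (heteroskedasticity-robust):
the linear probability model for caseness is intrinsically heteroskedastic,
so robust errors are the conservative convention; classical and CR1
cluster-robust (e.g. by county or state) variants are available. Confidence
intervals are the normal approximation ±1.96·SE, appropriate at survey
sample sizes. Binary outcomes are fitted by the identical estimator and
reported in percentage points (×100).

Weak-instrument policy: the excluded-instrument F for one instrument equals
the squared first-stage t-statistic under the selected covariance. Below
F = 1 the 2SLS estimate is refused (a `WeakInstrumentError` carrying F);
below F = 10 — the conventional bar — the fit is returned but flagged and a
warning emitted. Every output row carries its n and first-stage F; the
pipeline never reports a naked second stage.

Degenerate inputs: rank-deficient designs raise an error naming the
collinear columns (QR with column pivoting); a zero-variance instrument
raises a degenerate-instrument error; more than one excluded instrument is
rejected as unsupported (no over-identified GMM/LIML, matching the study
design).

## Synthetic population

The generator emulates the study's data structure with a known truth so the
pipeline can be validated end to end.

**Census.** Each county draws an adoption year uniformly over the rollout
span (default 1945–1992) and a coverage level from Beta(4, 2); a fraction
(default 25%) never adopts. Coverage is a step function (0 before adoption,
the county level after); a linear ramp-up variant exists because real
within-county trajectories after adoption are not well characterised —
constant is the default.

**Structural model.** For respondent i with exposure Z_i (computed by the
same accumulation rule the analysis uses), unobserved confounder
U_i ~ N(0, 1), and covariate shifts (gender, birth-year trend, state
effects):

    T*_i  = base + pi*Z_i + gamma_T*U_i + covariates + eps_i,  eps ~ N(0, sd_T)
    count = clamp(round(T*), 0, 28);  additionally, full edentulism (all 28)
            occurs with probability expit((T* - 20)/4) — a distinct clinical
            endpoint (full-mouth extraction), not the tail of the count noise
    bracket = None / 1–5 / 6–27 / All;  c = midpoint coding (0, 3, 16.5, 28)
    D_i   = alpha + beta*c_i + gamma_Y*U_i + covariates + nu_i

The depression equation carries `beta` on the midpoint-coded count `c` — the
scale the analyst's regressions use — so the 2SLS estimand equals `beta`
exactly and the OLS omitted-variable bias has the closed form

    bias_OLS = gamma_Y * cov(c~, U) / var(c~)

(tildes denote residuals on the covariate design). Bracket discretisation
leaves no elementary closed form for the moments of `c`, so the formula is
evaluated by plug-in on large auxiliary draws (six independent censuses ×
200 000 respondents under fixed internal seeds, giving ≲0.5% error in the
slope); the value is stored in each dataset's `TruthRecord` sidecar, which
the estimation modules never read. `calibrate_confounding` inverts the same
formula to set `gamma_Y` for a requested bias.

**PHQ items.** Item day-counts are Binomial(14, p_j) with logistic links
p_j(d) = expit((d − a_j)/b) in the latent depression score; item offsets a_j
are spread so symptoms differ in severity thresholds, and per-item treatment
loadings allow wiring the causal effect through a subset of items. The
latent score is first passed through the inverse of the expected-total curve
S(d) = E[scored total | d], which makes E[PHQ-8 total | D] = D exactly on
the interior of (0, 24): scoring is integer, noisy and monotone, yet
mean-unbiased — without this calibration every regression slope would be
attenuated by the average derivative of S and no generator parameter could
be recovered exactly.

**Presets.** `default_config` sits on the survey's scale: mean coded tooth
loss ≈ 4.5, about 2% edentulous, mean PHQ-8 ≈ 3.4 with the realistic skew
toward 0, and a first-stage slope of about half a tooth per full exposure —
which makes the instrument *weak* at desk-scale n (F ≈ 25 at n = 60 000),
exactly as in real data, where only very large samples make this design
informative. `recovery_config` is the strong-instrument regime used for
estimator validation: first-stage latent slope −3 teeth, latent depression
centred mid-scale at 12 (so clamping of the 0–24 score cannot attenuate
slopes), noise reduced, and `gamma_Y` calibrated so bias_OLS = +0.05. Under
it, 500 replicates at n = 5000 recover the true beta = 0.15 (2SLS) and
0.20 (OLS) within Monte-Carlo error, and 95% CIs cover the truth at 95.2%
over 1000 replicates at n = 2000. Monte-Carlo study sizes (500×5000,
1000×2000) were chosen to make the 2-MC-SE recovery bands a few thousandths
of a PHQ point wide while keeping the full suite runnable in minutes.

**What the generator does not emulate.** BRFSS sampling weights and
nonresponse, real US county geography and migration, within-county
water-system heterogeneity, item-level missingness patterns, and
serial/spatial correlation of depression. Passing tests therefore validate
the estimator and pipeline mechanics, not the substantive findings on real
survey data.

## Pipeline conventions

* Complete-case analysis: respondents outside the 1940–1978 birth cohort,
  with any missing/out-of-range PHQ item, or with an invalid bracket are
  excluded, and every exclusion step is counted in the audit log.
* The edentulous contrast compares "all teeth lost" against "≥1 tooth
  remaining" within respondents who lost at least one tooth; full-dentition
  respondents are outside the comparison group.
* Stratified analyses (age, birth cohort, gender, income, dental-care
  utilisation) are fitted independently per stratum; a degenerate stratum is
  marked unestimable and the run continues. The age split defaults to 50
  (the sample-mean age) and the cohort split to 1959 (the cohort midpoint);
  both are explicit in the emitted settings. No multiple-testing adjustment
  is applied to stratified intervals; the report says so by carrying the
  full settings block.
* Sensitivity codings (e.g. clinically derived mean/median/mode tooth
  counts for the middle brackets) are configuration inputs, not constants:
  the package does not invent values. Linearity of 2SLS in T implies an
  affine recoding rescales the estimate by the inverse slope — a tested
  invariant, and the reason smaller middle-bracket values yield larger
  second-stage estimates.
* Day→score thresholds for PHQ items default to the published BRFSS/PHQ-8
  convention (0–1 → 0, 2–6 → 1, 7–11 → 2, 12–14 → 3) and are configurable.
* Determinism: all randomness flows from explicit integer seeds through
  per-purpose `SeedSequence` streams; identical config + seed give
  byte-identical outputs.

## Known limitations

* Respondents are observed only in their current county; childhood exposure
  is computed as if they never moved (non-systematic misclassification).
* The estimator supports exactly one excluded instrument; over-identified
  or nonlinear (probit/logit) IV is out of scope.
* The analytic OLS-bias value is a high-precision plug-in, not a symbolic
  closed form; its residual Monte-Carlo error (≈0.5% relative) is far below
  the recovery tolerances but not zero.
* Survey weights are not implemented (the design under study does not use
  them), so population-level generalisation from weighted surveys is not
  supported.
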