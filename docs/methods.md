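# Methods

This note documents the models implemented in `tkrcea`, the calibration of
the synthetic registry the package ships in place of the (non-public) linked
national datasets, the numerical choices that affect results, and the known
limitations. Defaults live in `tkrcea/config.py`; everything below is
overridable there or through the YAML run configuration.

## Decision problem and model structure

Five cemented, unconstrained, fixed-bearing knee-prosthesis brands are
compared on lifetime costs (healthcare perspective, 2011–12 GBP) and QALYs
for patients with osteoarthritis entering at surgery, in six subgroups
(men/women × ages 60/70/80). The decision model is a cohort Markov chain
with a one-year cycle and four states:

1. **Primary TKR** — intact first implant; utility is the case-mix-adjusted
   6-month post-operative EQ-5D-3L index for the brand × subgroup, assumed
   to persist (less the aging decline) until revision or death.
2. **Revision year** — occupied for exactly one cycle when an implant is
   revised; utility from the pre-operative scores of revision patients.
3. **Revised TKR** — after recuperation; utility from 6-month post-revision
   scores; subject to re-revision, which returns the patient to state 2.
4. **Dead** — absorbing.

Cycle 0 applies operative mortality (0.002, brand-independent — no
across-brand difference is modelled) and the initial cost
(prosthesis price + £2 022 theatre + length-of-stay × £332). Each later
cycle applies, in order: background mortality, then revision transitions
among survivors. Each entry to the revision state incurs £8 429. Costs and
QALYs are discounted at 3.5%/year over 45 cycles. No half-cycle correction
is applied, so every aggregate is an exact finite sum reproducible
bit-for-bit (the unit-utility, no-event, discounted case equals the 45-term
annuity 23.2828). Re-revision cycles are unlimited. Utilities in every state
decline by 0.004·(age/70)² per year of age, floored at the instrument
minimum (−0.594).

## Input models

**Post-operative QOL.** OLS of the 6-month EQ-5D-3L index on brand
(treatment-coded against AGC Biomet, the lowest-cost brand), case mix (age,
sex, comorbidity count, BMI, disability, ASA grade, deprivation quintile,
patella replacement, surgical position, pre-operative EQ-5D and OKS) and
provider covariates (senior surgeon, treatment centre). Continuous
covariates are screened with fractional polynomials: FP1/FP2 over powers
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 = log), adopted only when deviance
improves on both the linear and the quadratic form by more than 4.605 (the
10% χ² point on 2 df; quadratic replaces linear at 3.84 on 1 df). The
functional forms are selected once, on the first completed dataset, and held
fixed across imputations so coefficients pool coherently. Subgroup
predictions set brand/sex/age and hold all other covariates at training
means. OKS is modelled in parallel for reporting only; EQ-5D feeds the
decision model.

**Missing data.** Post-operative outcomes (17% missing by default, MCAR or
MAR-on-covariates) are imputed with chained equations (predictive mean
matching via statsmodels), m = 20 datasets, 10 cycles each; estimates and
full coefficient covariance matrices are combined by Rubin's rules
(total covariance = mean within + (1 + 1/m) × between).

**Revision survival.** A flexible parametric model per brand: restricted
cubic spline in log time on the log-cumulative-hazard scale plus linear
covariate effects (age, sex, ASA 3, BMI, patella replacement, antibiotic
cement, provider flags), fitted by maximum likelihood (BFGS with analytic
gradients on a QR-orthonormalized spline basis; covariance from the inverse
finite-difference observed information). Three internal knots at the
10th/50th/90th percentiles of uncensored log event times, boundary knots at
the extremes. Beyond the boundary knot the restricted spline is linear in
log time, which is what extrapolates revision risk over the 45-year horizon.
Annual transition probabilities are p_t = [S(t−1) − S(t)]/S(t−1), which
telescope exactly to the cumulative incidence. Monotonicity of the fitted
cumulative hazard is checked on a grid and warned about, not silently fixed.
The cumulative-hazard-scale realization was chosen (over a hazard-scale
spline) because it yields closed-form survival and stable extrapolation.

**Re-revision.** Piecewise-exponential with one cut at 1 year (rate =
events/person-years per piece; SE of the log rate = 1/√events). The same
class with yearly cuts up to each brand's maximum follow-up serves as the
scenario-4 alternative revision model.

**Mortality.** Default life table is Gompertz, q(a) = 1 − exp(−B·e^(0.095a)),
with B calibrated per sex so remaining life expectancy at 70 is 14.0 y (men)
/ 16.0 y (women), close to contemporary UK national tables; any CSV table
(age, sex, qx) can be substituted. q is forced to 1 at age 110. The
healthy-patient effect multiplies q by RR(t) = 1 − (1 − RR₀)·exp(−t/2.35)
with RR₀(a) = 1 − 0.7(a − 40)/40 clamped to [0.3, 1]: a man aged 80 has
RR₀ = 0.3, the advantage is larger at older ages, and RR(10) ≥ 0.99. Only
the age-80 anchor and the decade-long decay are externally given; the linear
RR₀ schedule and exponential form are package choices.

## Probabilistic sensitivity analysis

1 000 draws by default. Regression and spline coefficient vectors are drawn
multivariate normal from their fitted (Rubin-pooled, where applicable)
covariances; re-revision rates log-normal; state-utility predictions normal
on the prediction scale; length of stay normal around its group mean.
Prosthesis prices and unit costs are contract values and are not sampled.
Draws are shared across brands within a simulation, so per-draw brand
comparisons are coherent; estimation stages fitted on different datasets are
treated as independent. Non-positive-definite covariances are repaired by
eigenvalue flooring and logged. The ICER ladder sorts by mean cost, removes
simply and extendedly dominated options (exact ties broken by brand name),
and reports ICERs between successive frontier members; acceptability
frontiers report, for each willingness-to-pay in £0–£50 000 (step £500),
the brand with the highest mean NMB and the share of draws in which it is
maximal.

**Scenarios.** (1) brand differences in post-operative QOL last one year:
from cycle 1 the primary-state utility is the unweighted across-brand mean
profile, per draw; (2) brand × age and brand × sex interactions in the QOL
regression; (3) pre-operative QOL entered as quintile-bin indicators — the
synthetic schema carries the EQ-5D index, not its five dimensions, so bins
of the index stand in for dimension dummies while preserving the point of
the scenario (relaxing linearity of the baseline-QOL adjustment);
(4) piecewise-constant revision hazards (yearly cuts) instead of the spline;
(5) every brand priced at the across-brand mean (£1 456).

## Synthetic registry calibration

The generator emulates the study conditions, not any patient-level data.
Case-mix marginals per brand (age ≈ 69.9–70.5, SD 7.3, truncated 55–84;
43–45% male; BMI ≈ 31.0–31.4; ASA-3 16–18%; deprivation; pre-operative
EQ-5D ≈ 0.38–0.41 and OKS ≈ 18.5–19.0) match the published cohort table.
Brand assignment runs through a provider layer — 400 synthetic hospitals,
each using one dominant brand for 90% of patients, treatment-centre and
consultant rates following the hospital's brand — so brand is correlated
with provider characteristics but independent of patient covariates given
provider, making confounding-by-provider testable.

The 6-month EQ-5D is a linear predictor (centred covariates; effects in
`QOL_TRUTH_COEF`) plus a brand offset and Gaussian noise, truncated to the
instrument support. Two calibration details matter:

* **Noise SD 0.25**, set so the OLS brand-contrast SE at n = 53 126 with the
  published brand shares is ≈ 0.004–0.005 — the precision a national PROMs
  sample delivers, and what makes the PSA win-probabilities realistic.
* **Ceiling censoring.** Truncation at EQ-5D = 1 censors ~13% of the noise
  mass, which would shift observed means down ~0.016 and shrink contrasts
  ~15%. Brand targets are therefore defined on the *observed* scale
  (AGC men-70 mean 0.72; offsets +0.01/+0.02/−0.01/0 for PFC
  Sigma/Nexgen/Genesis 2/Triathlon; −0.01 for women) and the latent mean is
  solved from the censored-normal mean formula, per brand × sex. The same
  correction applies to the revision-state utilities (anchors 0.45 and 0.62
  at age 70).

Revision event times come from a two-piece hazard (year 1 vs later) solved
exactly so cumulative incidence at 5 and 10 years hits the published
brand × sex rates at the age-70 reference profile, multiplied by
proportional effects of centred covariates; accrual is uniform with
administrative censoring at each brand's maximum observation period
(11.1 y for PFC Sigma and 6.7 y for Triathlon are known; AGC 10.5,
Nexgen 9.5, Genesis 2 8.5 are interpolated package defaults). Re-revision
times use rates (0.04, 0.015)/person-year. Mean length of stay per
brand × sex is back-computed from the published mean primary-episode costs
(e.g. AGC men 4.223 days, so 1 150 + 2 022 + 4.223 × 332 = £4 574), with
gamma noise (SD 2.5 days).

What the generator does **not** emulate: EQ-5D dimension profiles and the
discrete/skewed shape of real utility data (noise is censored Gaussian);
within-hospital outcome correlation beyond the provider flags; time trends
in surgical practice; informative (outcome-dependent) missingness; rising
late-life implant failure beyond the constant post-year-1 hazard. Passing
tests therefore demonstrate that the estimators recover the structure they
assume at registry scale — not that the assumptions hold in real registries.

## Problem sizes used in tests and reproduction

The acceptance script and end-to-end tests run the generator at the study's
own scale (53 126 QOL records, 239 945 survival records, 1 000 PSA draws);
unit and property tests use 1 200–60 000 records, chosen as the smallest
sizes at which the checked effects are resolvable against 3-SE bounds. The
cohort engine is validated against an independent individual-level
microsimulation (100 000+ patients) kept in the test suite.

## Numerical choices

Spline fitting uses a QR-orthonormalized basis (raw cubic bases are too
ill-conditioned for quasi-Newton optimization); the transform is stored and
applied at every prediction. Survival probabilities are clipped to [0, 1]
and 0/0 cycles (survival already exhausted) resolve to probability 1.
Degenerate inputs fail loudly: non-positive times, all-missing columns,
rank-deficient designs (offending terms listed), cumulative-incidence
targets ≥ 1 or decreasing, unknown scenario/mechanism labels. All-censored
survival pieces yield rate 0 with a warning. Every stochastic component
takes an explicit seed; identical seeds reproduce byte-identical datasets
and draws.

## Known limitations

* Incremental lifetime costs are sensitive to what a revision episode costs
  and to extrapolated late-life revision risk. With the flat £8 429 episode
  cost and the constant post-year-1 truth hazard, the model concentrates
  brand differences in the initial episode; analyses that additionally cost
  revision bed-days, or whose fitted hazards rise late in life, attribute
  more of the lifetime cost difference to revisions and so report lower
  incremental cost-effectiveness ratios for the QALY-leading brand. The
  Nexgen-vs-AGC ICER here centres roughly 15–20% above a model with those
  features; the ranking and the acceptability conclusions are unaffected.
* Provider clustering is represented only through two provider flags; no
  hierarchical model is fitted, so between-hospital variance in outcomes is
  understated.
* The healthy-patient effect and the life table are parametric conveniences
  anchored at a few published values; absolute QALY levels (though not brand
  increments, which share the mortality schedule) depend on them.
* Competing causes of revision (septic vs aseptic) are not distinguished;
  revision-state utilities are assumed identical either way.
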