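# Methods

This note documents the models implemented in `mipdsim`, the reasoning
behind the shipped defaults, the numerical choices, and what the synthetic
study does and does not show about real patients.

## Pharmacokinetic model

A one-compartment model with first-order elimination describes infliximab
(an IgG1 monoclonal antibody) disposition over the 84-day induction
window. Doses are modelled as IV bolus events; over an 84-day AUC horizon
the difference from a 2-hour infusion is negligible for a drug with a
~10-day half-life, and the bolus assumption gives exact piecewise-
exponential closed forms for both the concentration and the partial AUC.

Covariates enter clearance multiplicatively: an allometric power on
fat-free mass (exponent 0.75, volume exponent 1.0 — the conventional
three-quarter-power scaling), and factors for corticosteroid use,
extensive colitis, and a baseline Mayo endoscopic subscore of 3. The
Mayo-3 factor (> 1) encodes the systematically lower exposure of severely
active disease, mechanistically attributed to target-mediated clearance
and fecal drug loss through the inflamed mucosa.

Random effects: interindividual variability (IIV) on the elimination rate
constant (applied through clearance) and on volume; interoccasion
variability (IOV) on the elimination rate constant only, with occasions
defined as the dosing intervals [0, 14), [14, 42) and [42, 84] days. IOV
on elimination is the minimal structure consistent with a model whose
time-varying disease covariates (CRP, albumin) were deliberately removed:
what those covariates explained must reappear as within-patient
variability. Residual error is proportional on the linear concentration
scale; simulated observations are floored at zero.

## Exposure–response model

Endoscopic state at day 84 is ordinal (Mayo subscore ≤ 1, = 2, = 3) and is
reached sequentially: a baseline-3 patient must transition to the moderate
state before improving. Each transition probability is a hyperbolic Emax
function of AUC_d84 with plateau `Emax` and half-maximal exposure `AUC50`
(hill exponent configurable, default 1). The bounded plateaus encode
intrinsic non-response: beyond a point, more drug cannot help. The
hyperbola (rather than a bounded logistic) is used because `AUC50` is
defined as the half-maximal exposure, which the hyperbola carries as an
explicit parameter; the form fixes p(0) = 0 (no placebo response).

The likelihood of (AUC, baseline, outcome) records separates exactly into
a binomial term for the 3→2 transition (baseline-3 records) and one for
the 2→≤1 transition (baseline-2 records plus baseline-3 records that
reached ≤ 2). `fit_auc50` therefore profiles each AUC50 by a 1-D bounded
minimisation on log(AUC50) (deterministic 81-point coarse grid followed by
bounded Brent refinement), and the likelihood-profile surface over an
(Emax,3→2, Emax,2→1/0) grid is the outer sum of two 1-D profiles. The 95%
confidence region is bounded by Δ2LL = 3.84, the χ² (1 df) 95th
percentile; region edges are refined by linear interpolation along grid
edges. Default grid: 0.70–1.00 in steps of 0.02, which brackets the
published contour endpoints.

## Synthetic population

The source covariate table emulates a 194-patient induction cohort:

| quantity | default | rationale |
|---|---|---|
| baseline Mayo 3 fraction | 0.51 | published 49:51 split (largest-remainder rounding: 95/99) |
| body weight | log-normal, mean 72.3 kg, CV 20% | mean implied by 1084 mg mean cumulative dose at 3 × 5 mg/kg |
| height | sex-specific normal (176 ± 7 / 163 ± 6.5 cm) | typical adult anthropometry |
| sex | 50% male | ulcerative colitis has no strong sex skew |
| fat-free mass | Janmahasatian formula | realistic covariance with weight and sex |
| steroid use, extensive colitis | Bernoulli(0.5) each | prevalences unpublished; uninformed defaults, configurable |

Weight–height draws in which the body-composition formula would give
fat-free mass ≥ 95% of weight (implausibly tall-and-light tails) are
rejected and redrawn. Random effects are drawn independently of
covariates. The expansion step draws, per virtual patient, independent
η_ke, η_V and one κ per occasion.

What the generator does *not* emulate: covariate correlations with disease
severity, time-varying disease markers, immunogenicity (anti-drug
antibodies), dropout, or measurement timing deviations. Passing tests
therefore demonstrate properties of the dosing algorithms under the
assumed popPK/ER models — not predictions about any real cohort.

## Calibration of the shipped defaults

The clinical parameter estimates underlying this study design are not
publicly available, so the defaults here are calibration artefacts, not
estimates. `scripts/calibrate_defaults.py`
solves, by Brent root-finding on a large virtual population (2000 source
patients × 100 expansions, fixed seeds):

* `cl_typ` → Mayo-2 stratum median AUC_d84 at 5 mg/kg = 2455 mg·day/L,
* `theta_mayo3_cl` → Mayo-3 stratum median = 1979 mg·day/L
  (the solved factor, 1.279, implies the published exposure ratio
  2455/1979 ≈ 1.24 after mixing over the other covariates),
* `omega_ke` → Mayo-2 P95/P5 exposure ratio = 4805/1215,

in two passes to absorb the weak coupling introduced by the day-84
truncation. Calibrating against a large population means the defaults
target the *distribution's* operating points; a single 194-patient cohort
then scatters around them with ~3% (1 sd) covariate-sampling noise on the
stratum medians, which is why regression tests of the calibration pool
several replicate cohorts. Remaining fixed choices: `v_typ` = 5 L
(plasma-like volume of an IgG at the reference fat-free mass of 50 kg),
`omega_v` = 0.15, `omega_iov_ke` = 0.15, `sigma_prop` = 0.25 — typical
magnitudes for monoclonal-antibody popPK models of this structure.

The ER defaults use the selected "most pessimistic" plateau pair
(Emax,3→2 = 1.0, Emax,2→1/0 = 0.784). The two AUC50s are solved in closed
form so the model passes through the 5 mg/kg operating points
(pEI 61.2% at AUC 2455 for Mayo 2; 50.3% at 1979 for Mayo 3), giving
AUC50(2→1) ≈ 690 and AUC50(3→2) ≈ 308 mg·day/L. For sensitivity-analysis
pairs the AUC50s are re-solved through the same operating points,
mirroring that all models on the confidence contour fit the observed
exposure range equally well and differ only in extrapolation.

## Dose individualisation

**Targets.** Stratum-specific medians of the paired 10 mg/kg run (not one
combined median): exposure and efficacy targets differ by baseline
severity, and a combined target would systematically overdose Mayo-2 and
underdose Mayo-3 patients.

**A priori dose.** AUC is exactly linear in dose, so the covariate-based
dose is `target / Σ_k a_k`, where `a_k` is the per-mg AUC coefficient of
infusion k at zero random effects.

**MAP update.** The day-14 pre-dose trough (simulated from the truth plus
proportional residual error) feeds the penalised objective
`Σ η²/ω² + κ₁²/ω_IOV² + ((c_obs − c_pred)/(σ·c_pred))²`. By default
η_ke, η_V and κ₁ are estimated jointly — a single observation cannot
separate them, but shrinkage resolves the weak identifiability; an
η_ke-only mode is available (`estimate=("eta_ke",)`). Internally the fit
is reduced analytically to at most two dimensions: η_ke and κ₁ enter the
prediction only through their sum s, whose prior penalty is
`s²/(ω_ke² + ω_IOV²)`; the mode splits s across the two effects in
proportion to their prior variances. The 2-D problem is solved by
L-BFGS-B with analytic gradients from two deterministic starts (the prior
mode and the observation-implied s at η_V = 0). Degenerate inputs: all
prior variances zero → the prior mode is returned without fitting;
σ = 0 (exact observation) → the prior penalty is minimised on the
constraint curve c_pred = c_obs (closed form when η_V is not estimated,
1-D bounded search otherwise); a zero or flat-likelihood trough returns
the prior mode.

**Dose adaptation.** Doses 2 and 3 are set to the common value
`(target − AUC(dose 1)) / (a₂ + a₃)` at the MAP individual parameters with
future-occasion deviations at their prior mean (zero) — the forecaster
cannot know future occasion shifts — floored at 0 with a logged warning if
dose 1 alone already exceeds the target. No dose rounding and no upper
cap: real-world dose banding is a translation issue outside this model.
Efficacy is always evaluated at the *attained* (truth) AUC, not the
forecast.

## Numerical and design choices

* Prediction intervals are 5th–95th percentiles ("90% PI"), linear
  interpolation convention; the level is a parameter of `summarize`.
* Combined summary rows pool the realised strata (≈ 49:51 weighting).
* Paired design: one virtual population underlies all four scenarios, so
  scenario contrasts are within-patient; the trough residual draw is the
  only scenario-specific randomness, seeded separately.
* Per-patient probabilities (not Bernoulli draws) quantify efficacy: the
  population mean is identical, and the sd then measures between-patient
  inequality of chances rather than binomial noise.
* All seeds derive from `numpy.random.SeedSequence` spawning, keeping
  every derived seed below 2³¹.
* Closed-form kinetics are verified against independent ODE
  (`solve_ivp`, rtol 1e-11) and trapezoidal-quadrature oracles; the MAP
  optimiser against dense grid searches.

## Problem sizes used in the test suite

Unit and property tests run on a 194 × 20 population (3,880 virtual
patients). The variance-reduction ordering is checked on 20 independent
replicates of that size; calibration regression pools ten 194 × 50
cohorts; the ER contour coverage check uses 100 replicates of 800 records.
The acceptance script runs the full 194 × 200 = 38,800-patient design.

## Known limitations

* All defaults downstream of the calibration anchors are conditional on
  invented covariate distributions; absolute dose numbers (mg) shift with
  the weight distribution, though paired scenario contrasts are robust.
* The ER model assumes a causal exposure→response relation and no placebo
  response; transition plateaus are extrapolations beyond the exposure
  range that any feasible induction dose explores.
* The forecaster sees exactly one noiseless-timing trough; sampling-time
  error and assay limits of quantification are not modelled.
* Baseline Mayo subscore is kept as a PK covariate by default; set
  `theta_mayo3_cl = 1` to remove it (its role in the re-estimated source
  model is ambiguous).
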