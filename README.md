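# mipdsim

In-silico comparison of infliximab induction dosing strategies for patients
with moderate-to-severe ulcerative colitis.

Infliximab induction therapy (infusions at days 0, 14 and 42) fails
endoscopically in roughly half of patients, and exposure — the area under
the serum concentration–time curve up to endoscopy at day 84, AUC_d84 —
correlates with endoscopic improvement (Mayo endoscopic subscore ≤ 1).
`mipdsim` is a simulation laboratory for the question that follows: does
model-informed precision dosing (MIPD), which individualises doses using a
population pharmacokinetic (popPK) model, improve outcomes over flat
weight-based dosing — and at what drug cost? It is aimed at
pharmacometricians and clinical-pharmacology researchers who want a fully
reproducible virtual trial of induction dosing strategies.

## Models

**Pharmacokinetics.** One-compartment IV bolus model with first-order
elimination. Individual clearance and volume follow the standard
nonlinear-mixed-effects covariate idiom,

```
CL_ik = CL_typ · (FFM_i/FFM_ref)^θ_FFM,CL · θ_ster^[steroid] · θ_ext^[extensive]
        · θ_Mayo3^[Mayo=3] · exp(η_ke,i + κ_ik)
V_i   = V_typ · (FFM_i/FFM_ref)^θ_FFM,V · exp(η_V,i)
ke_ik = CL_ik / V_i
```

with interindividual variability (η, log-normal) on the elimination rate
constant and volume, interoccasion variability (κ) on the elimination rate
constant per dosing interval, and proportional residual error on observed
concentrations. Concentrations and AUC_d84 have exact closed forms
(piecewise exponentials), so dose proportionality holds exactly.

**Exposure–response.** A sequential ordinal model with bounded maxima:
severe disease (Mayo 3) must pass through moderate (Mayo 2) before reaching
improvement (≤ 1). Each transition follows a hyperbolic Emax curve in
AUC_d84, `p = Emax · AUC/(AUC50 + AUC)`, so the probability of endoscopic
improvement is `pEI = p_21` from baseline Mayo 2 and `pEI = p_32 · p_21`
from baseline Mayo 3. The plateaus `Emax,3→2` and `Emax,2→1/0` encode
intrinsic non-responders; their joint 95% confidence region is obtained by
likelihood profiling (Δ2LL = 3.84, the χ²₁ 95th percentile).

**Dosing scenarios.** Four paired scenarios on the same virtual patients:
5 mg/kg, 10 mg/kg, covariate-based MIPD (a priori), and concentration-based
MIPD (the day-14 trough feeds a MAP empirical-Bayes update that adapts
doses 2 and 3). Both MIPD arms target, per baseline stratum, the median
AUC_d84 of the 10 mg/kg scenario.

The original clinical covariate table is not public, so a synthetic source
cohort (n = 194, Mayo 2:3 ≈ 49:51, log-normal weights, fat-free mass from
the Janmahasatian formula) stands in for it, expanded by 200 Monte Carlo
samples of the random effects to 38,800 virtual patients. Default PK
parameters are calibration artefacts solved so the 5 mg/kg scenario
reproduces the published stratum medians; see `docs/methods.md`.

## Worked example

```python
from mipdsim import (default_poppk_params, default_er_params,
                     default_cohort_config, generate_source_cohort,
                     expand_virtual, run_all, summarize)

poppk = default_poppk_params()
er = default_er_params()
cfg = default_cohort_config()

cohort = generate_source_cohort(cfg, seed=101)          # 194 source patients
population = expand_virtual(cohort, poppk, cfg.n_expand, seed=202)
results = run_all(population, poppk, er, seed=303)      # four paired scenarios

table = summarize(results).query("stratum == 'combined'")
cols = ["scenario", "auc_median", "auc_lo", "auc_hi",
        "pei_mean", "pei_sd", "dose_mean"]
print(table[cols].round(2).to_string(index=False))
```

prints

```
          scenario  auc_median  auc_lo  auc_hi  pei_mean  pei_sd  dose_mean
             5mgkg     2137.02 1020.17 4417.16      0.54    0.09    1078.61
            10mgkg     4274.03 2040.34 8834.32      0.64    0.06    2157.22
    covariate_mipd     4305.51 2212.63 7966.62      0.64    0.06    2159.45
concentration_mipd     4408.50 3058.83 6719.08      0.65    0.04    2358.93
```

Reading the table: doubling the flat dose doubles the median exposure
(mg·day/L) and lifts the mean probability of endoscopic improvement from
0.54 to 0.64. Covariate-based MIPD achieves the same median exposure and
mean pEI at a visibly narrower 90% prediction interval (`auc_lo`–`auc_hi`),
and trough-guided Bayesian forecasting narrows it much further
(3059–6719 vs 2040–8834) and cuts the between-patient sd of pEI roughly in
half — but consumes more drug on average (2359 mg vs 2157 mg per patient):
individualisation is not a zero-sum redistribution of dose.

A command-line interface wraps the same pipeline:

```
mipdsim make-cohort --out cohort.csv
mipdsim simulate --out-dir run/ --seed 1
mipdsim profile-er --data records.csv --out profile.csv
```

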