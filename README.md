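# restrictmi

Restriction-aware multiple imputation for longitudinal categorical
exposures with forward-only transitions — and the simulation machinery to
evaluate it.

## The problem

Longitudinal studies often measure categorical exposures whose transitions
are logically restricted. The motivating case is maternal smoking recorded
at repeated waves as never-smoker (0), ex-smoker (1) or current-smoker (2):
an ex- or current-smoker can never become a never-smoker at a later wave.
When such a variable has missing waves — common under attrition — standard
multiple imputation (MI) happily imputes impossible ever→never transitions,
and it is not obvious how much that distorts downstream estimates.

`restrictmi` is aimed at biostatisticians studying missing-data methods for
longitudinal cohorts. It implements:

* a **cohort simulator** for a child-cohort structure: time-independent
  covariates, an autoregressive binary auxiliary (maternal depression),
  smoking at waves 0–6 generated by a two-branch transition model that
  enforces the forward-only restriction by construction, and a continuous
  outcome (BMI-for-age z-score, BMIz, waves 2–6) from a random-intercept
  linear model with lagged smoking as the exposure;
* **calibrated missingness mechanisms** for smoking waves 1–5: a monotone
  dropout model (Model A) and an intermittent model (Model B), MCAR or MAR
  through depression and next-wave BMIz, with per-wave intercepts solved by
  root-finding to hit configured overall proportions (45% or 65%);
* a **three-stage semi-deterministic restriction procedure**: cells before
  an observed never-smoker are backfilled deterministically (stage 1),
  cells after an observed ever-smoker are imputed on {ex, current}
  (stage 2), and the rest are imputed unrestricted (stage 3), with
  residual violations audited;
* **MI engines**: fully conditional specification (multinomial, ordinal,
  predictive mean matching with k donors and type-1/2 matching), the
  two-fold time-windowed FCS variant, and multivariate-normal imputation
  with two categorical-recovery schemes (indicator coding + projected
  distance-based rounding; continuous coding + rank calibration);
* the **analysis layer**: random-intercept linear mixed model (profiled
  REML), complete-case and available-case variants, Rubin's rules pooling;
* an **evaluation harness** computing bias, relative bias, empirical and
  model-based SE, coverage, MSE, Monte Carlo error and non-convergence
  rates over a scenario grid.

## The target analysis

For subject *i* at wave *j* = 2,…,6:

```
BMIz_ij = (β₀ + b_0i) + β₁,₁·[smoke_{i,j-1}=ex] + β₁,₂·[smoke_{i,j-1}=cur]
          + β₂·age_ij + … + β₈·ses_i + ε_ij,
b_0i ~ N(0, σ_b²),   ε_ij ~ N(0, σ_ε²)
```

with never-smoker as the reference. The generator uses β₁,₁ = 0.10 and
β₁,₂ = 0.15 as the true exposure effects; every study run is scored
against them.

## Worked example

Simulate one cohort, impose calibrated weak-MAR missingness at the extreme
(65%) level, impute with restriction-adapted FCS-PMM, and pool:

```python
import numpy as np
from restrictmi import (SimulationParams, simulate_cohort, MissingnessConfig,
                        calibrate_intercepts, impose_missingness,
                        ImputationSpec, impute_fcs, fit_cohort, cca_fit,
                        pool_results)
from restrictmi.restriction import assignment_for_cohort

params = SimulationParams(n_subjects=1000)
rng = np.random.default_rng(42)

config = MissingnessConfig(mechanism="MAR_weak", overall_target=0.65)
calib = [simulate_cohort(params, r) for r in rng.spawn(5)]
intercepts = calibrate_intercepts(calib, config)

cohort = simulate_cohort(params, rng)
masked, mask = impose_missingness(cohort, intercepts, config, rng)
assignment = assignment_for_cohort(masked)

stack = impute_fcs(masked, ImputationSpec(method="pmm", pmm_k=5, m=10),
                   assignment, rng)
pooled = pool_results([fit_cohort(c) for c in stack.imputations])
```

Output (seed 42):

```
missing smoking cells: 66.5%
stage counts: {1: 328, 2: 852, 3: 2146}
mean implausible transitions per imputation: 53.4
smoking_ex: 0.052 (SE 0.074, 95% CI -0.098 to 0.202)
smoking_cur: 0.073 (SE 0.067, 95% CI -0.061 to 0.206)
CCA retains 34 of 1000 subjects; beta_cur = -0.287 (SE 0.247)
```

Reading this: two thirds of the smoking cells at waves 1–5 are missing.
The restriction procedure resolves 328 cells deterministically (stage 1)
and narrows 852 to the binary ex/current choice (stage 2); only stage-3
draws can still produce implausible transitions (about 53 per completed
dataset, versus roughly double that without restrictions). The pooled MI
estimates for this single replicate sit below the truths (0.10, 0.15) —
single replicates are noisy, and the imputation-induced attenuation is
quantified properly over hundreds of replicates by the evaluation harness
— while complete-case analysis keeps only 34 subjects and is far less
stable. A command-line interface (`restrictmi simulate / ampute / impute /
analyze / run-study`) wraps the same pipeline for shell use.

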