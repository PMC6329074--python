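# Methods

This note documents the models, algorithms and design choices behind
`restrictmi`: what the synthetic cohorts emulate, how missingness is
calibrated, how each imputation engine works, how the analysis and pooling
are performed, and what the package's tests do and do not establish.

## 1. Generative model

Each cohort is a wide table of `n_subjects` (default 1000) subjects.

**Time-independent covariates.** Maternal age ~ N(31, 5²) years; maternal
education completed ~ Bernoulli(0.60); breastfeeding ~ Bernoulli(0.85);
family socio-economic status (ses) ~ N(0, 1) z-score; child sex male ~
Bernoulli(0.51); birthweight ~ N(3.40, 0.55²) kg; child age at waves 1–6
~ N(9, 33, 57, 81, 105, 129 months; SD 1). These are plausible values for
an Australian-style infant cohort followed biennially; all are
configurable through `CovariateParams`.

**Maternal depression** (binary auxiliary, waves 0–5) follows a
first-order autoregressive logistic model: wave 0 depends on ses and
maternal age (intercept −1.75, slopes −0.30 and −0.02/year); later waves
add a persistence term (+2.0 on the previous wave's status, intercept
−2.20). The autoregression gives depression the within-subject
persistence it needs to be a useful auxiliary variable for the MAR
mechanisms. Marginal prevalence is ≈ 16–17% at every wave.

**Maternal smoking** (never = 0, ex = 1, current = 2, waves 0–6):

* wave 0 (pregnancy) from a baseline-category multinomial logistic model
  on maternal age, education and ses; defaults give ≈ 76% never, 7% ex,
  17% current — smoking-in-pregnancy in the realistic 15–20% band with a
  small ex category;
* waves 1–6 by a two-branch transition model. Previous never-smokers face
  a three-category multinomial (initiation ≈ 2–4% per wave, with
  depression increasing and education/ses decreasing the odds); a
  never→ex step in one interval is allowed (start and quit between
  waves). Previous ever-smokers face a binary current-vs-ex draw whose
  logit includes +3.5 for having been current at the previous wave, so
  current-smokers persist (≈ 85%/wave) and ex-smokers occasionally
  relapse (≈ 15%/wave). Because this branch can only return ex or
  current, **no simulated trajectory can ever violate the forward-only
  restriction** — verified exhaustively in the tests.

**Outcome.** BMI-for-age z-scores at waves 2–6 from the random-intercept
linear model in the README, with the *previous* wave's smoking category
as the exposure. True exposure effects are β_ex = 0.10 and β_cur = 0.15
(BMIz units); the other fixed effects are small and conventional. Default
variance components σ_b = 0.8 and σ_ε = 0.6 give total BMIz variance
≈ 1.0 (it is a z-score) and an intra-class correlation of 0.64,
consistent with the strong tracking of child adiposity across ages.

Wave-6 smoking is generated for structural fidelity but is never made
missing and never enters the analysis (the last outcome wave, 6, uses the
wave-5 exposure). BMIz is generated only for waves 2–6, the waves with a
lagged exposure available.

**Randomness.** One master seed spawns independent `numpy` generator
streams per dataset and per method via `SeedSequence.spawn`, so every
scenario is reproducible and replicates are independent.

## 2. Missingness mechanisms and calibration

Missingness affects only smoking waves 1–5. Two logistic mechanisms act
in sequence:

* **Model A (dropout)**: per-wave incident hazard applied to subjects not
  yet dropped; once missing, missing at all later waves.
* **Model B (intermittent)**: independent per-wave gaps among cells still
  observed after Model A, so subjects can be observed again after a gap.

Under MAR, both logits depend on depression at the same wave and BMIz at
the next wave, with the odds ratios: weak MAR 1.67/1.64 (Model A) and
1.61/1.58 (Model B); strong MAR 2.80/2.60 and 2.70/2.50. Both sets are
stored verbatim; a helper constructs a strong configuration by exactly
doubling the weak log-odds, which is the defining relation between the
two strengths (the stored strong values are the conventionally rounded
published ones and differ from the exact squares in the second decimal).
Because both predictors are always observed, missingness is independent
of the unobserved smoking values given observed data — MAR holds by
construction. MCAR uses the same machinery with zero slopes, preserving
the monotone/intermittent mixture.

**Per-wave targets.** The overall proportion (0.45 realistic, 0.65
extreme) is spread over waves 1–5 as a linearly increasing schedule
(overall ± 0.20, 0.10, 0, steps of 0.10), mimicking accumulating
attrition. By default 60% of each wave's marginal target is routed
through dropout and 40% through the intermittent model, so both pathways
are exercised; both the schedule and the split are configurable.

**Calibration.** The intercepts are not free parameters. Given the slope
coefficients and a calibration sample of simulated cohorts, the per-wave
Model-A intercept is solved by bracketed root-finding (Brent) so the
weighted mean of expit(intercept + slopes·features) over the at-risk
population equals the incident dropout hazard implied by the schedule;
at-risk status is propagated deterministically through per-subject
survival probabilities rather than by drawing masks, removing calibration
noise. Model-B intercepts are then solved against the still-observed
weights. Unattainable schedules (a wave target below the dropout floor
inherited from earlier waves) raise a configuration error naming the
wave. Achieved proportions on independent validation samples match the
overall target well within ±1 percentage point.

## 3. Restriction procedure

For each subject, over waves 0–5 (wave 0 is always observed in the study
design; the classification window is configurable):

* **stage 1** — a later wave is observed never: the cell is never, filled
  deterministically and identically in every imputation;
* **stage 2** — an earlier wave is observed ex/current: the cell is
  imputed stochastically on {ex, current};
* **stage 3** — otherwise: imputed on the full three-category support.

Observed data that themselves violate the restriction raise an error. The
classification is deterministic, order-invariant, and tested against an
exhaustive cell-by-cell oracle. Stage-3 draws can still create
ever→never transitions; these are accepted (re-enforcing restrictions
inside already-restricted chains is deliberately out of scope) and
counted by an auditor over adjacent wave pairs 0–6. Only stage-3 cells
can originate violations; the paired comparison restricted-vs-standard
shows strictly fewer violations in aggregate, though individual replicate
pairs can fluctuate because the draws are stochastic.

Engine-specific realization of stage 2: parametric FCS imputers fit a
binary (ex vs current) model on the observed ever-smoker subsample; PMM
restricts the donor pool to observed ex/current values; MVNI-PDBR rounds
to the nearer of the two ever vertices; MVNI-calibration calibrates
within the observed ever-smoker stratum of the wave.

## 4. FCS engine

Wide-format chained equations ("just another variable"): the five
incomplete smoking columns are imputed wave by wave, each univariate
model conditioning on the current values of all other predictors — for
the standard engine, the other smoking waves 0–5 (as ex/current dummies),
all BMIz waves, all depression waves, child ages and the time-independent
covariates; this is the full analysis-variable set plus the auxiliary.
Chains are initialized by draws from observed marginals (restricted cells
from their allowed-support marginals). Defaults m = 20 imputations and 10
cycles — conventional for 45–65% missingness — both configurable
(`ImputationSpec`).

* **Multinomial / ordinal**: maximum-likelihood fits (baseline-category
  logistic; proportional-odds on the codes 0 < 1 < 2 in the unconstrained
  threshold parametrization, so posterior draws always have increasing
  cutpoints), with parameters drawn from the asymptotic normal
  approximation to the posterior — standard approximate proper imputation
  with no explicit prior. Perfect separation, empty categories, diverged
  (non-finite) estimates, iteration limits, or singular covariances raise
  a non-convergence signal. On full-size cohorts these engines fail
  essentially always: six strongly correlated categorical smoking
  predictors with a rare ex category quasi-separate the fits. The failure
  *accounting* (a dataset-level non-convergence flag; failed datasets
  excluded from summaries and reported as a rate) is the modelled
  behaviour; the numeric failure rate is implementation-specific.
* **PMM**: linear regression of the numeric codes; σ² drawn from the
  scaled inverse-χ², coefficients from N(β̂, σ²(XᵀX)⁻¹) via Cholesky.
  Type-1 matching predicts donors with β̂ and recipients with the draw;
  type-2 (default, matching the common single-equation implementation)
  uses the draw for both. Donor search exploits the 1-D structure: donors
  sorted by predicted mean, each recipient's k nearest form a contiguous
  window found by a vectorized scan; distance ties are broken by a seeded
  uniform jitter; one of the k donors is drawn uniformly. Imputed values
  are always observed codes. Fewer than k donors shrinks k with a
  warning; zero donors is a non-convergence.
* **Two-fold FCS**: outer sweeps over waves 1→5; each wave's multinomial
  model conditions only on the adjacent smoking waves and wave-0 smoking,
  depression at waves j−1..j+1, BMIz at waves j and j+1 (where they
  exist), and the time-independent covariates. Boundary waves use their
  single neighbour. The multinomial imputer is used (an ordinal variant
  is deliberately not offered, matching the standard implementation of
  the algorithm). The depression/BMIz windowing is a design choice; both
  follow the "same and adjacent waves" rule.

## 5. MVNI engine

All imputation-model variables are stacked into one matrix assumed
multivariate normal and sampled by data augmentation: an I-step drawing
each row's missing entries from their conditional normal given observed
entries and current (μ, Σ) — rows grouped by missingness pattern — and a
P-step drawing (μ, Σ) from the normal–inverse-Wishart posterior under a
Jeffreys-style prior, with a small ridge retry when a draw is numerically
singular (45–65% missingness over correlated dummies is fragile, and
occasional non-convergence is expected and flagged). Defaults: 200
burn-in iterations, 100 between saved imputations.

Categorical recovery, per wave:

* **indicator + PDBR**: two dummies per wave (d1 = ex, d2 = current);
  rounding returns the category whose vertex — (0,0) never, (1,0) ex,
  (0,1) current — is nearest in Euclidean distance, with seeded uniform
  tie-breaks. No attempt to preserve category proportions.
* **continuous + calibration**: one 0/1/2 code per wave; imputed values
  are ranked and cut so category counts follow the observed proportions
  of that wave by largest-remainder apportionment, guaranteeing
  |imputed − observed proportion| ≤ 1/n_mis per category. Calibration is
  per wave (each wave has its own observed marginal).

The asymmetry — calibration preserves marginals, PDBR does not — is the
structural reason the two schemes bias differently. Binary covariates
enter the normal model as 0/1 and are never re-imputed (complete by
design). Both schemes satisfy decode∘encode identity on complete data,
and the sampler is an exact identity when nothing is missing.

## 6. Analysis and pooling

The target model is fitted by REML, profiled for the random-intercept
structure: for a fixed variance ratio γ = σ_b²/σ_ε², the GLS estimate,
profiled residual variance and both log-determinants are closed-form via
group-wise Woodbury identities on precomputed group sums, leaving a
bounded 1-D optimization over log γ. A boundary comparison at γ = 0
handles singular fits (degrades to OLS). This is exact for the model
class and fast enough for the many thousands of fits the study grid
needs; coefficients and standard errors are cross-checked against
statsmodels MixedLM in the test suite (agreement to ≈ 1e-5 / 0.2%).
Model-based SEs are the GLS ones; intervals use t with residual degrees
of freedom (the reference treatment for CCA/ACA intervals, where no
pooling df applies).

* **CCA** drops every subject with any missing smoking wave 1–5.
* **ACA** drops only analysis rows whose lagged exposure is missing.
  CCA's rows are always a subset of ACA's, strictly under any
  intermittent pattern.

**Rubin's rules**: Q̄ = mean estimate, W = mean squared SE, B = between
variance (ddof 1), T = W + (1+1/m)B, df = (m−1)(1 + W/((1+1/m)B))² — the
original large-sample formula; with n = 1000 subjects the small-sample
correction would be negligible. B numerically zero falls back to the
complete-data df. Intervals are t-based.

## 7. Evaluation harness

`run_scenario` calibrates intercepts once per mechanism×proportion cell
on an independent sample (default 10 cohorts), then per replicate
simulates a cohort, imposes missingness, runs every requested
method×restriction combination on its own RNG stream, analyzes, pools and
records. Metrics per method and parameter: bias, relative bias (%),
empirical SE (SD of estimates), model-based SE (mean of SEs), 95%
coverage, MSE, Monte Carlo error of the bias (empSE/√R), and the
non-convergence rate; metrics use converged replicates only, and the
converged-only set is also the coverage denominator. Desk-scale presets
(100–200 replicates, m = 10) are used by the tests and the acceptance
script; all sizes are configurable.

## 8. Numerical choices

* PMM design ridge 1e-8·tr(XᵀX)/p for rank safety; posterior draws via
  triangular solves (no explicit inverses).
* Posterior covariance draws add escalating jitter before Cholesky and
  raise non-convergence after four failures.
* Multinomial/softmax draws subtract the row max before exponentiation.
* Brent root-finding for calibration uses analytic brackets
  [logit(p) − max η, logit(p) − min η], which always contain the root.
* Distance/rank ties (PMM donors, PDBR vertices) are broken by seeded
  uniform draws, keeping runs reproducible.

## 9. What the synthetic study does and does not show

The generator reproduces the *structure* of the motivating cohort — wave
layout, restricted transitions, a rare middle category, outcome-dependent
MAR through an always-observed auxiliary — but its coefficient values are
plausible stand-ins, not estimates from any real cohort. Passing tests
establish that the machinery is correct (calibration hits its targets;
classification matches the exhaustive oracle; donor pools match brute
force; pooling matches hand computation; proper imputation under the true
model is unbiased), not that any MI method is unbiased on real data.

Two substantive behaviours of this regime are worth knowing:

* **PMM attenuation.** Under the default generative parameters,
  restriction-adapted FCS-PMM still attenuates the exposure coefficients
  by roughly 15–28% (relative) at 45–65% missingness. An exact-posterior
  oracle imputation is unbiased on the same masked datasets, so this is
  not a pipeline defect: a single linear index on the codes 0/1/2 cannot
  represent the three-category conditional well enough, and the rare ex
  group is diluted by stage-3 false positives whose BMIz carries no
  exposure signal. How large this attenuation is depends strongly on the
  generative coefficients; regimes with stronger exposure–outcome or
  exposure–predictor associations show less.
* **Over-coverage for the rare category.** Pooled intervals for the
  ex-smoker coefficient over-cover (≈ 97–100% at nominal 95%) because
  between-imputation variance is large for the rare category; the
  current-smoker coefficient covers near nominally.

Other known limitations: no multilevel (random-effects) imputation
models; no MNAR mechanisms; missingness only in the smoking exposure;
rounding methods are the two standard single-time-point schemes applied
wave-wise.
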