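"""Complete-cohort simulator.

Generates wide-format cohorts (one row per subject) with:

* time-independent covariates drawn from configured distributions,
* maternal depression from a first-order autoregressive logistic model,
* maternal smoking at wave 0 from a multinomial logistic model, and at
  waves 1..6 from a two-branch transition model — a three-category
  multinomial for previous never-smokers and a binary current-vs-ex
  logistic for previous ever-smokers — which makes the forward-only
  restriction (ever-smoker never returns to "never") hold by construction,
* BMI-for-age z-scores at waves 2..6 from a random-intercept linear model
  with the previous wave's smoking category as the exposure of interest.

All draws are vectorized over subjects and deterministic given the
generator passed in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .params import (
    BMIZ_COLS,
    CURRENT,
    EX,
    NEVER,
    SimulationParams,
)

__all__ = [
    "simulate_covariates",
    "simulate_smoking_wave0",
    "simulate_smoking_transition",
    "simulate_bmiz",
    "simulate_cohort",
]


def simulate_covariates(params: SimulationParams,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw time-independent covariates, wave ages and depression waves 0..5."""
    params.validate()
    cov = params.covariates
    n = params.n_subjects
    out = pd.DataFrame({
        "m_age": rng.normal(cov.m_age_mean, cov.m_age_sd, n),
        "m_education": (rng.random(n) < cov.m_education_prev).astype(np.int64),
        "breastfed": (rng.random(n) < cov.breastfed_prev).astype(np.int64),
        "ses": rng.normal(cov.ses_mean, cov.ses_sd, n),
        "sex": (rng.random(n) < cov.sex_prev).astype(np.int64),
        "birthweight": rng.normal(cov.birthweight_mean, cov.birthweight_sd, n),
    })
    for j, mean in enumerate(cov.scage_means, start=1):
        out[f"scage{j}"] = rng.normal(mean, cov.scage_sd, n)

    base = cov.dep_b_ses * out["ses"].to_numpy() \
        + cov.dep_b_age * (out["m_age"].to_numpy() - 30.0)
    dep_prev = np.zeros(n)
    for j in range(6):
        icpt = cov.dep_intercept0 if j == 0 else cov.dep_intercept
        persist = 0.0 if j == 0 else cov.dep_b_prev * dep_prev
        p = expit(icpt + base + persist)
        dep = (rng.random(n) < p).astype(np.int64)
        out[f"m_depression{j}"] = dep
        dep_prev = dep
    return out


def _multinomial_draw(logits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw categories 0..K from per-row logits of categories 1..K vs baseline 0."""
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite linear predictor in multinomial draw")
    full = np.concatenate([np.zeros((logits.shape[0], 1)), logits], axis=1)
    full -= full.max(axis=1, keepdims=True)
    probs = np.exp(full)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(logits.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)


def simulate_smoking_wave0(covariates: pd.DataFrame,
                           coefs,
                           rng: np.random.Generator) -> np.ndarray:
    """Smoking during pregnancy from a baseline-category multinomial model."""
    X = np.column_stack([
        np.ones(len(covariates)),
        covariates["m_age"].to_numpy(),
        covariates["m_education"].to_numpy(),
        covariates["ses"].to_numpy(),
    ])
    logits = X @ np.asarray(coefs, dtype=float).T   # (n, 2): ex, current
    return _multinomial_draw(logits, rng)


def simulate_smoking_transition(prev_category: np.ndarray,
                                covariates: pd.DataFrame,
                                depression_prev: np.ndarray,
                                never_coefs,
                                ever_coefs,
                                rng: np.random.Generator) -> np.ndarray:
    """One wave-to-wave transition honouring the forward-only restriction.

    Previous never-smokers face a three-category multinomial; previous
    ever-smokers a binary draw between staying/becoming a current-smoker
    (category 2) and being an ex-smoker (category 1). The output can equal
    0 only when the previous category was 0.
    """
    prev = np.asarray(prev_category)
    if not np.isin(prev, (NEVER, EX, CURRENT)).all():
        raise ValueError("previous smoking category outside {0,1,2}")
    n = len(prev)
    out = np.empty(n, dtype=np.int64)

    m_age = covariates["m_age"].to_numpy()
    m_educ = covariates["m_education"].to_numpy()
    ses = covariates["ses"].to_numpy()
    dep = np.asarray(depression_prev, dtype=float)

    from_never = prev == NEVER
    if from_never.any():
        X = np.column_stack([
            np.ones(from_never.sum()),
            m_age[from_never],
            m_educ[from_never],
            dep[from_never],
            ses[from_never],
        ])
        logits = X @ np.asarray(never_coefs, dtype=float).T
        out[from_never] = _multinomial_draw(logits, rng)

    from_ever = ~from_never
    if from_ever.any():
        k = np.asarray(ever_coefs, dtype=float)
        logit = (k[0]
                 + k[1] * m_age[from_ever]
                 + k[2] * m_educ[from_ever]
                 + k[3] * dep[from_ever]
                 + k[4] * (prev[from_ever] == CURRENT)
                 + k[5] * ses[from_ever])
        is_current = rng.random(from_ever.sum()) < expit(logit)
        out[from_ever] = np.where(is_current, CURRENT, EX)
    return out


def simulate_bmiz(cohort: pd.DataFrame,
                  params: SimulationParams,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Outcome waves 2..6 from the random-intercept linear model.

    BMIz_{ij} = (b0 + b_{0i}) + b_ex[smoking_{j-1}=1] + b_cur[smoking_{j-1}=2]
                + covariate terms + e_{ij}, with b_{0i} shared across waves.
    """
    n = len(cohort)
    b0i = rng.normal(0.0, params.random_intercept_sd, n)
    fixed_time_indep = (
        params.beta_intercept
        + params.beta_breastfed * cohort["breastfed"].to_numpy()
        + params.beta_m_age * cohort["m_age"].to_numpy()
        + params.beta_m_education * cohort["m_education"].to_numpy()
        + params.beta_birthweight * cohort["birthweight"].to_numpy()
        + params.beta_sex * cohort["sex"].to_numpy()
        + params.beta_ses * cohort["ses"].to_numpy()
    )
    out = cohort.copy()
    for j in range(2, 7):
        smoking_lag = cohort[f"m_smoking{j-1}"].to_numpy()
        mean = (fixed_time_indep + b0i
                + params.beta_smoking_ex * (smoking_lag == EX)
                + params.beta_smoking_cur * (smoking_lag == CURRENT)
                + params.beta_scage * cohort[f"scage{j}"].to_numpy())
        out[f"BMIz{j}"] = mean + rng.normal(0.0, params.residual_sd, n)
    return out


def simulate_cohort(params: SimulationParams,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate one complete cohort table.

    The returned frame has no missing values and satisfies the forward-only
    restriction in every trajectory.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cohort = simulate_covariates(params, rng)
    cohort["m_smoking0"] = simulate_smoking_wave0(
        cohort, params.smoking_wave0_coefs, rng)
    for j in range(1, 7):
        prev = cohort[f"m_smoking{j-1}"].to_numpy()
        dep_prev = cohort[f"m_depression{min(j - 1, 5)}"].to_numpy()
        cohort[f"m_smoking{j}"] = simulate_smoking_transition(
            prev, cohort, dep_prev,
            params.never_transition_coefs, params.ever_transition_coefs, rng)
    cohort = simulate_bmiz(cohort, params, rng)
    cohort.index.name = "subject_id"
    return cohort


def check_forward_only(smoking: np.ndarray) -> bool:
    """True iff no trajectory steps from an ever category back to never."""
    s = np.asarray(smoking)
    return not ((s[:, :-1] != NEVER) & (s[:, 1:] == NEVER)).any()


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=True)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")
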