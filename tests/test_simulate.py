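"""Cohort simulator: distributions, transition structure, outcome model."""

import numpy as np
import pandas as pd
import pytest

from restrictmi import SimulationParams, simulate_cohort
from restrictmi.params import ConfigurationError, CovariateParams
from restrictmi.simulate import (
    check_forward_only,
    simulate_bmiz,
    simulate_covariates,
    simulate_smoking_transition,
    simulate_smoking_wave0,
)


def _constant_covariates(n, m_age=30.0, m_education=1.0, ses=0.0):
    return pd.DataFrame({
        "m_age": np.full(n, m_age), "m_education": np.full(n, m_education),
        "breastfed": np.ones(n), "ses": np.full(n, ses),
        "sex": np.zeros(n), "birthweight": np.full(n, 3.4),
    })


def test_same_seed_gives_identical_cohorts(params):
    a = simulate_cohort(params, np.random.default_rng(5))
    b = simulate_cohort(params, np.random.default_rng(5))
    pd.testing.assert_frame_equal(a, b)


def test_cohort_shape_and_completeness(cohort):
    assert len(cohort) == 1000
    for j in range(7):
        assert cohort[f"m_smoking{j}"].isin([0, 1, 2]).all()
    for j in range(2, 7):
        assert np.isfinite(cohort[f"BMIz{j}"]).all()
    assert not cohort.isna().any().any()


def test_forward_only_restriction_holds_everywhere():
    params = SimulationParams(n_subjects=100_000)
    big = simulate_cohort(params, np.random.default_rng(9))
    smoking = big[[f"m_smoking{j}" for j in range(7)]].to_numpy()
    assert check_forward_only(smoking)


def test_wave0_probabilities_match_softmax_oracle():
    n = 100_000
    cov = _constant_covariates(n, m_age=28.0, m_education=1.0, ses=0.5)
    coefs = np.array([[-1.0, 0.02, -0.3, -0.2],
                      [0.5, -0.04, -0.5, -0.4]])
    x = np.array([1.0, 28.0, 1.0, 0.5])
    logits = np.concatenate([[0.0], coefs @ x])
    expected = np.exp(logits) / np.exp(logits).sum()
    draws = simulate_smoking_wave0(cov, coefs, np.random.default_rng(3))
    freq = np.bincount(draws, minlength=3) / n
    se = np.sqrt(expected * (1 - expected) / n)
    assert np.all(np.abs(freq - expected) < 3 * se)

    flat = simulate_smoking_wave0(cov, np.zeros((2, 4)),
                                  np.random.default_rng(4))
    freq = np.bincount(flat, minlength=3) / n
    assert np.all(np.abs(freq - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n))


def test_transitions_from_ever_never_return_to_never():
    n = 50_000
    cov = _constant_covariates(n, m_age=0.0, m_education=0.0, ses=0.0)
    dep = np.zeros(n)
    rng = np.random.default_rng(6)
    zeros5 = np.zeros((2, 5))
    # all-zero coefficients from prev=ex: P(current) = 0.5, never 0
    out = simulate_smoking_transition(np.ones(n, dtype=int), cov, dep,
                                      zeros5, np.zeros(6), rng)
    assert not (out == 0).any()
    p_cur = (out == 2).mean()
    assert abs(p_cur - 0.5) < 3 * np.sqrt(0.25 / n)
    # persistence odds ratio: prev=current vs prev=ex with kappa_4 = ln 3
    kappa = np.array([0.0, 0.0, 0.0, 0.0, np.log(3.0), 0.0])
    from_cur = simulate_smoking_transition(np.full(n, 2), cov, dep,
                                           zeros5, kappa, rng)
    assert not (from_cur == 0).any()
    p_stay = (from_cur == 2).mean()
    assert abs(p_stay - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n)


def test_transitions_from_never_match_multinomial_oracle():
    n = 100_000
    cov = _constant_covariates(n, m_age=30.0, m_education=0.0, ses=0.0)
    dep = np.ones(n)
    zeta = np.array([[-2.0, 0.01, -0.3, 0.5, -0.2],
                     [-1.0, -0.02, -0.4, 0.6, -0.3]])
    x = np.array([1.0, 30.0, 0.0, 1.0, 0.0])
    logits = np.concatenate([[0.0], zeta @ x])
    expected = np.exp(logits) / np.exp(logits).sum()
    out = simulate_smoking_transition(np.zeros(n, dtype=int), cov, dep,
                                      zeta, np.zeros(6),
                                      np.random.default_rng(8))
    freq = np.bincount(out, minlength=3) / n
    se = np.sqrt(expected * (1 - expected) / n)
    assert np.all(np.abs(freq - expected) < 3 * se)


def test_transition_rejects_invalid_previous_category():
    cov = _constant_covariates(3)
    with pytest.raises(ValueError):
        simulate_smoking_transition(np.array([0, 1, 7]), cov, np.zeros(3),
                                    np.zeros((2, 5)), np.zeros(6),
                                    np.random.default_rng(0))


def test_bmiz_noiseless_limit_returns_intercept():
    params = SimulationParams(
        n_subjects=50, beta_smoking_ex=0.0, beta_smoking_cur=0.0,
        beta_scage=0.0, beta_breastfed=0.0, beta_m_age=0.0,
        beta_m_education=0.0, beta_birthweight=0.0, beta_sex=0.0,
        beta_ses=0.0, beta_intercept=0.3,
        random_intercept_sd=0.0, residual_sd=1e-12)
    cohort = simulate_covariates(params, np.random.default_rng(1))
    for j in range(7):
        cohort[f"m_smoking{j}"] = 0
    out = simulate_bmiz(cohort, params, np.random.default_rng(2))
    for j in range(2, 7):
        assert np.allclose(out[f"BMIz{j}"], 0.3, atol=1e-9)


def test_bmiz_random_intercept_variance_decomposition():
    # sigma_b = sigma_e = 1 and no fixed effects: Var = 2, within-corr = 0.5
    params = SimulationParams(
        n_subjects=100_000, beta_smoking_ex=0.0, beta_smoking_cur=0.0,
        beta_scage=0.0, beta_breastfed=0.0, beta_m_age=0.0,
        beta_m_education=0.0, beta_birthweight=0.0, beta_sex=0.0,
        beta_ses=0.0, beta_intercept=0.0,
        random_intercept_sd=1.0, residual_sd=1.0)
    out = simulate_cohort(params, np.random.default_rng(12))
    var = out["BMIz4"].var()
    corr = np.corrcoef(out["BMIz3"], out["BMIz5"])[0, 1]
    assert abs(var - 2.0) < 0.05
    assert abs(corr - 0.5) < 0.01


def test_bmiz_mean_shift_for_current_smokers():
    # beta_cur = 0.15 with all other effects off: mean difference = 0.15
    params = SimulationParams(
        n_subjects=100_000, beta_smoking_ex=0.0, beta_smoking_cur=0.15,
        beta_scage=0.0, beta_breastfed=0.0, beta_m_age=0.0,
        beta_m_education=0.0, beta_birthweight=0.0, beta_sex=0.0,
        beta_ses=0.0, beta_intercept=0.0,
        random_intercept_sd=0.5, residual_sd=0.5)
    out = simulate_cohort(params, np.random.default_rng(13))
    lag = out["m_smoking3"].to_numpy()
    diff = out.loc[lag == 2, "BMIz4"].mean() - out.loc[lag == 0, "BMIz4"].mean()
    assert abs(diff - 0.15) < 0.02


def test_depression_symmetric_logistic_gives_half_prevalence():
    cov = CovariateParams(dep_intercept0=0.0, dep_intercept=0.0,
                          dep_b_ses=0.0, dep_b_age=0.0, dep_b_prev=0.0)
    params = SimulationParams(n_subjects=100_000, covariates=cov)
    out = simulate_covariates(params, np.random.default_rng(14))
    for j in range(6):
        prev = out[f"m_depression{j}"].mean()
        assert abs(prev - 0.5) < 3 * np.sqrt(0.25 / len(out))


def test_depression_absorbing_persistence_limit():
    cov = CovariateParams(dep_intercept0=50.0, dep_intercept=-50.0,
                          dep_b_ses=0.0, dep_b_age=0.0, dep_b_prev=100.0)
    params = SimulationParams(n_subjects=2000, covariates=cov)
    out = simulate_covariates(params, np.random.default_rng(15))
    for j in range(6):
        assert (out[f"m_depression{j}"] == 1).all()


def test_covariate_moments_match_configuration():
    params = SimulationParams(n_subjects=100_000)
    cov = params.covariates
    out = simulate_covariates(params, np.random.default_rng(16))
    n = len(out)
    assert abs(out["m_age"].mean() - cov.m_age_mean) \
        < 3 * cov.m_age_sd / np.sqrt(n)
    for col, p in (("m_education", cov.m_education_prev),
                   ("breastfed", cov.breastfed_prev),
                   ("sex", cov.sex_prev)):
        assert abs(out[col].mean() - p) < 3 * np.sqrt(p * (1 - p) / n)
    assert abs(out["birthweight"].std() - cov.birthweight_sd) < 0.01


@pytest.mark.parametrize("bad", [
    dict(n_subjects=0),
    dict(residual_sd=0.0),
    dict(random_intercept_sd=-1.0),
    dict(covariates=CovariateParams(breastfed_prev=1.5)),
])
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ConfigurationError):
        SimulationParams(**bad).validate()
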