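"""Chained-equation engine: univariate imputers and the FCS driver."""

import numpy as np
import pandas as pd
import pytest

from restrictmi import fcs
from restrictmi.fcs import (
    ImputationSpec,
    NonConvergenceError,
    _nearest_donor_pick,
    impute_fcs,
    impute_multinomial,
    impute_ordinal,
    impute_pmm,
    impute_two_fold,
)


# --- PMM -------------------------------------------------------------------


def test_pmm_single_donor_is_forced_choice():
    rng = np.random.default_rng(0)
    y = np.array([2.0, 2.0, 2.0])
    X = np.array([[1.0], [1.0], [1.0]])
    out = impute_pmm(y, X, np.ones((5, 1)), k=1, matching_type=2, rng=rng)
    assert (out == 2.0).all()


def test_pmm_donor_pool_matches_brute_force_nearest_k():
    rng = np.random.default_rng(5)
    yhat_d = rng.normal(size=120)
    yhat_r = rng.normal(size=30)
    for k in (1, 3, 5):
        picks = np.array([_nearest_donor_pick(yhat_d, yhat_r, k, rng)
                          for _ in range(800)])
        for i in range(len(yhat_r)):
            nearest = set(np.argsort(np.abs(yhat_d - yhat_r[i]))[:k])
            assert set(picks[:, i]) == nearest   # subset and full coverage


def test_pmm_imputes_only_observed_codes(weak65):
    spec = ImputationSpec(method="pmm", m=2, n_cycles=2)
    stack = impute_fcs(weak65["masked"], spec, None, np.random.default_rng(1))
    assert stack.converged
    for imp in stack.imputations:
        for j in range(1, 6):
            assert imp[f"m_smoking{j}"].isin([0, 1, 2]).all()


def test_pmm_zero_donors_raises():
    rng = np.random.default_rng(0)
    y = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
    X = np.column_stack([np.ones(6), np.arange(6.0)])
    with pytest.raises(NonConvergenceError):
        impute_pmm(y, X, np.ones((2, 2)), k=3, matching_type=2, rng=rng,
                   donor_mask=np.zeros(6, bool))


def test_pmm_small_donor_pool_shrinks_k_with_warning():
    rng = np.random.default_rng(0)
    y = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
    X = np.column_stack([np.ones(6), np.arange(6.0)])
    with pytest.warns(RuntimeWarning, match="donor pool smaller"):
        impute_pmm(y, X, X[:2], k=10, matching_type=2, rng=rng)


# --- parametric imputers ---------------------------------------------------


def test_multinomial_intercept_only_reproduces_marginals():
    rng = np.random.default_rng(3)
    props = np.array([0.6, 0.1, 0.3])
    y = rng.choice([0, 1, 2], size=3000, p=props)
    X = np.ones((3000, 1))
    draws = impute_multinomial(y, X, np.ones((100_000, 1)), rng)
    observed = np.bincount(y, minlength=3) / len(y)
    freq = np.bincount(draws, minlength=3) / len(draws)
    # posterior draw adds O(1/sqrt(n_fit)) wobble around observed marginals
    se = np.sqrt(observed * (1 - observed)) \
        * np.sqrt(1 / len(draws) + 1 / len(y))
    assert np.all(np.abs(freq - observed) < 4 * se)


def test_ordinal_weak_predictor_reproduces_marginals():
    rng = np.random.default_rng(4)
    props = np.array([0.5, 0.2, 0.3])
    y = rng.choice([0, 1, 2], size=3000, p=props)
    X = np.column_stack([np.ones(3000), rng.normal(size=3000)])
    X_mis = np.column_stack([np.ones(50_000), rng.normal(size=50_000)])
    draws = impute_ordinal(y, X, X_mis, rng)
    observed = np.bincount(y, minlength=3) / len(y)
    freq = np.bincount(draws, minlength=3) / len(draws)
    se = np.sqrt(observed * (1 - observed)) \
        * np.sqrt(1 / len(draws) + 1 / len(y))
    assert np.all(np.abs(freq - observed) < 4 * se)


def test_ordinal_positive_effect_shifts_draws_upward():
    rng = np.random.default_rng(6)
    z = rng.normal(size=4000)
    latent = 2.0 * z + rng.logistic(size=4000)
    y = np.digitize(latent, [-1.0, 1.0])
    X = np.column_stack([np.ones(4000), z])
    lo = impute_ordinal(y, X, np.tile([1.0, -2.0], (4000, 1)), rng)
    hi = impute_ordinal(y, X, np.tile([1.0, 2.0], (4000, 1)), rng)
    assert hi.mean() > lo.mean() + 0.5


def test_separation_and_empty_category_raise_nonconvergence():
    rng = np.random.default_rng(7)
    x = np.concatenate([np.full(50, -2.0), np.full(50, 0.0), np.full(50, 2.0)])
    y = np.repeat([0, 1, 2], 50)          # x separates the classes perfectly
    X = np.column_stack([np.ones(150), x])
    with pytest.raises(NonConvergenceError):
        impute_multinomial(y, X, X[:5], rng)
    y_empty = np.repeat([0, 2], 75)       # no ex-smokers at all
    with pytest.raises(NonConvergenceError):
        impute_multinomial(y_empty, np.ones((150, 1)), np.ones((5, 1)), rng)
    with pytest.raises(NonConvergenceError):
        impute_ordinal(y_empty, np.ones((150, 1)), np.ones((5, 1)), rng)


# --- driver ----------------------------------------------------------------


def test_no_missing_cells_returns_input(cohort):
    spec = ImputationSpec(method="pmm", m=3, n_cycles=2)
    stack = impute_fcs(cohort, spec, None, np.random.default_rng(8))
    assert stack.converged and stack.m == 3
    for imp in stack.imputations:
        for j in range(6):
            assert (imp[f"m_smoking{j}"].to_numpy()
                    == cohort[f"m_smoking{j}"].to_numpy()).all()


def test_same_seed_gives_identical_stack(weak65):
    spec = ImputationSpec(method="pmm", m=2, n_cycles=2)
    a = impute_fcs(weak65["masked"], spec, None, np.random.default_rng(9))
    b = impute_fcs(weak65["masked"], spec, None, np.random.default_rng(9))
    for ia, ib in zip(a.imputations, b.imputations):
        pd.testing.assert_frame_equal(ia, ib)


def test_observed_cells_identical_across_imputations(weak65):
    masked = weak65["masked"]
    spec = ImputationSpec(method="pmm", m=3, n_cycles=2)
    stack = impute_fcs(masked, spec, None, np.random.default_rng(10))
    for j in range(1, 6):
        obs = masked[f"m_smoking{j}"].notna()
        for imp in stack.imputations:
            assert (imp.loc[obs, f"m_smoking{j}"].to_numpy()
                    == masked.loc[obs, f"m_smoking{j}"].to_numpy()).all()


def test_multinomial_fcs_fails_on_rich_wide_models(weak65):
    """Six correlated categorical smoking predictors with a rare category
    make the multinomial fits separate, which must surface as a
    dataset-level non-convergence flag rather than silent output."""
    spec = ImputationSpec(method="multinomial", m=2, n_cycles=2)
    stack = impute_fcs(weak65["masked"], spec, None, np.random.default_rng(11))
    assert not stack.converged
    assert stack.imputations == []
    two = impute_two_fold(weak65["masked"],
                          ImputationSpec(m=2, n_cycles=2),
                          None, np.random.default_rng(12))
    assert not two.converged


def test_two_fold_window_for_middle_wave(weak65):
    ws = fcs._Workspace(weak65["masked"], two_fold=True)
    assert ws.predictor_waves(3) == [0, 2, 4]
    # intercept + 6 time-independent + depression waves 2..4 + BMIz 3,4
    assert ws.static[3].shape[1] == 12
    assert ws.design(3).shape[1] == 12 + 3 * 2
    # boundary wave: single neighbour, single feasible BMIz pair
    assert ws.predictor_waves(1) == [0, 2]
    assert ws.predictor_waves(5) == [0, 4]


@pytest.mark.parametrize("bad", [
    dict(m=1), dict(n_cycles=0), dict(pmm_k=0),
    dict(pmm_matching_type=3), dict(method="bogus"),
])
def test_invalid_spec_rejected(bad):
    with pytest.raises(ValueError):
        ImputationSpec(**bad)
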