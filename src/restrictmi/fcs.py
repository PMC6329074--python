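"""Fully conditional specification (chained-equations) imputation.

The incomplete variables are the smoking categories at waves 1..5, treated
as distinct columns of the wide table ("just another variable"). Missing
cells are initialized by draws from the observed marginals, then updated by
``n_cycles`` sweeps of wave-wise univariate imputation, each conditioning
on the current values of every other predictor. Three univariate imputers
are available:

* ``multinomial`` — baseline-category logistic fit by ML, parameters drawn
  from the asymptotic normal posterior approximation;
* ``ordinal`` — proportional-odds model on the codes 0 < 1 < 2;
* ``pmm`` — predictive mean matching: linear regression of the numeric
  codes, a posterior parameter draw, and donor selection among the k
  observed cases nearest in predicted mean (type-1 or type-2 matching).

The three-stage restriction procedure plugs in through a
:class:`~restrictmi.restriction.StageAssignment`: stage-1 cells are filled
deterministically before imputation, stage-2 cells are imputed on the
binary ex/current support (parametric fits on the ever-smoker subsample;
PMM donor pools restricted to observed ever-smokers), and stage-3 cells use
the unrestricted three-category machinery.

A univariate fitting failure (perfect separation, empty category, singular
design, iteration limit) flags the whole dataset as non-converged, matching
how simulation studies account for imputation failures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import cho_solve, solve_triangular
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .params import (
    CURRENT,
    EX,
    MISSING_WAVES,
    NEVER,
    TIME_INDEPENDENT,
)
from .restriction import (
    STAGE2,
    STAGE3,
    RestrictionReport,
    StageAssignment,
    apply_stage1,
    audit_violations,
)

Method = Literal["multinomial", "ordinal", "pmm"]


class NonConvergenceError(RuntimeError):
    """Signals a univariate imputation model that could not be fitted."""


@dataclass
class ImputationSpec:
    method: Method = "pmm"
    pmm_k: int = 5
    pmm_matching_type: int = 2     # 2: posterior draw on both sides;
    #                                1: donors predicted with the ML fit
    m: int = 20
    n_cycles: int = 10
    two_fold: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least m=2 imputations")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.pmm_k < 1:
            raise ValueError("pmm_k must be >= 1")
        if self.pmm_matching_type not in (1, 2):
            raise ValueError("pmm_matching_type must be 1 or 2")
        if self.method not in ("multinomial", "ordinal", "pmm"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ImputedStack:
    """m completed copies of a cohort plus per-copy diagnostics."""
    imputations: list[pd.DataFrame]
    converged: bool
    reports: list[RestrictionReport] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.imputations)


# ---------------------------------------------------------------------------
# design-matrix assembly


def _smoking_dummies(smoking: np.ndarray, waves: Sequence[int]) -> np.ndarray:
    cols = []
    for w in waves:
        s = smoking[:, w]
        cols.append((s == EX).astype(float))
        cols.append((s == CURRENT).astype(float))
    return np.column_stack(cols) if cols else np.empty((smoking.shape[0], 0))


class _Workspace:
    """Numpy working copy of the cohort for fast chained sweeps."""

    def __init__(self, cohort: pd.DataFrame, two_fold: bool):
        self.n = len(cohort)
        self.two_fold = two_fold
        self.smoking = cohort[[f"m_smoking{j}" for j in range(6)]].to_numpy(float)
        self.static = {}
        ti = cohort[list(TIME_INDEPENDENT)].to_numpy(float)
        dep = cohort[[f"m_depression{j}" for j in range(6)]].to_numpy(float)
        bmiz = cohort[[f"BMIz{j}" for j in range(2, 7)]].to_numpy(float)
        scage = cohort[[f"scage{j}" for j in range(2, 7)]].to_numpy(float)
        ones = np.ones((self.n, 1))
        for wave in MISSING_WAVES:
            if two_fold:
                # window: depression j-1..j+1 (clipped to 0..5) and BMIz at
                # waves j and j+1 (those that exist), plus time-independent
                # covariates; smoking neighbours are added dynamically
                dep_idx = [w for w in (wave - 1, wave, wave + 1) if 0 <= w <= 5]
                bz_idx = [w - 2 for w in (wave, wave + 1) if 2 <= w <= 6]
                block = [ones, ti, dep[:, dep_idx]]
                if bz_idx:
                    block.append(bmiz[:, bz_idx])
                self.static[wave] = np.column_stack(block)
            else:
                self.static[wave] = np.column_stack(
                    [ones, ti, scage, dep, bmiz])

    def predictor_waves(self, wave: int) -> list[int]:
        if self.two_fold:
            waves = [0]
            if wave - 1 > 0:
                waves.append(wave - 1)
            if wave + 1 <= 5:
                waves.append(wave + 1)
            return sorted(set(waves))
        return [w for w in range(6) if w != wave]

    def design(self, wave: int) -> np.ndarray:
        dummies = _smoking_dummies(self.smoking, self.predictor_waves(wave))
        return np.column_stack([self.static[wave], dummies])


# ---------------------------------------------------------------------------
# univariate imputers


def _posterior_draw(params: np.ndarray, cov: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw from N(params, cov), regularizing a near-singular covariance."""
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov))):
        raise NonConvergenceError("non-finite parameter covariance")
    cov = (cov + cov.T) / 2.0
    jitter = 0.0
    scale = max(np.abs(np.diag(cov)).max(), 1e-12)
    for _ in range(4):
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * scale)
    else:
        raise NonConvergenceError("parameter covariance not positive definite")
    return params + L @ rng.standard_normal(len(params))


def _categorical_draw(probs: np.ndarray, categories: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    cum = probs.cumsum(axis=1)
    cum /= cum[:, -1:]
    idx = (cum < rng.random(len(probs))[:, None]).sum(axis=1)
    return categories[idx]


def impute_multinomial(y_obs: np.ndarray, X_obs: np.ndarray,
                       X_mis: np.ndarray, rng: np.random.Generator,
                       categories: Sequence[int] = (NEVER, EX, CURRENT),
                       ) -> np.ndarray:
    """Baseline-category multinomial imputer with a posterior parameter draw."""
    categories = np.asarray(sorted(categories))
    counts = np.array([(y_obs == c).sum() for c in categories])
    if (counts == 0).any():
        raise NonConvergenceError("empty category in the fitting sample")
    if len(categories) == 2:
        return _impute_binary_logit(y_obs, X_obs, X_mis, rng, categories)
    codes = np.searchsorted(categories, y_obs)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(codes, X_obs).fit(method="newton", maxiter=100,
                                               disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
        raise NonConvergenceError(f"multinomial fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise NonConvergenceError("multinomial iteration limit reached")
    if not np.all(np.isfinite(np.asarray(res.params))):
        raise NonConvergenceError("multinomial estimates diverged (separation)")
    draw = _posterior_draw(np.asarray(res.params).ravel(order="F"),
                           res.cov_params(), rng)
    B = draw.reshape(res.params.shape, order="F")   # (p, K-1)
    logits = np.column_stack([np.zeros(len(X_mis)), X_mis @ B])
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    return _categorical_draw(probs, categories, rng)


def _impute_binary_logit(y_obs, X_obs, X_mis, rng, categories):
    target = (y_obs == categories[1]).astype(int)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(target, X_obs).fit(method="newton", maxiter=100,
                                              disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
        raise NonConvergenceError(f"binary logit fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise NonConvergenceError("binary logit iteration limit reached")
    if not np.all(np.isfinite(np.asarray(res.params))):
        raise NonConvergenceError("logit estimates diverged (separation)")
    draw = _posterior_draw(res.params, res.cov_params(), rng)
    p1 = 1.0 / (1.0 + np.exp(-(X_mis @ draw)))
    return np.where(rng.random(len(X_mis)) < p1, categories[1], categories[0])


def impute_ordinal(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
                   rng: np.random.Generator,
                   categories: Sequence[int] = (NEVER, EX, CURRENT),
                   ) -> np.ndarray:
    """Proportional-odds imputer on the ordered codes.

    The model is fitted in the unconstrained threshold parametrization, so a
    normal posterior draw always yields strictly increasing cutpoints.
    """
    categories = np.asarray(sorted(categories))
    if any((y_obs == c).sum() == 0 for c in categories):
        raise NonConvergenceError("empty category in the fitting sample")
    if len(categories) == 2:
        return _impute_binary_logit(y_obs, X_obs, X_mis, rng, categories)
    # OrderedModel forbids an explicit constant; column 0 is the intercept
    X_o, X_m = X_obs[:, 1:], X_mis[:, 1:]
    codes = np.searchsorted(categories, y_obs)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(codes, X_o, distr="logit")
            res = model.fit(method="bfgs", maxiter=200, disp=0)
    except (np.linalg.LinAlgError, ValueError, RuntimeError) as exc:
        raise NonConvergenceError(f"ordinal fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise NonConvergenceError("ordinal fit did not converge")
    draw = _posterior_draw(np.asarray(res.params), res.cov_params(), rng)
    probs = np.asarray(model.predict(draw, exog=X_m))
    if not np.all(np.isfinite(probs)):
        raise NonConvergenceError("ordinal predicted probabilities not finite")
    return _categorical_draw(probs, categories, rng)


def impute_pmm(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
               k: int, matching_type: int, rng: np.random.Generator,
               donor_mask: np.ndarray | None = None) -> np.ndarray:
    """Predictive mean matching on the numeric codes.

    Type-1 matching predicts donors with the ML estimate and recipients
    with the posterior draw; type-2 uses the draw for both. Ties in
    predictive distance are broken by a seeded uniform choice.
    """
    n_obs, p = X_obs.shape
    if n_obs - p <= 0:
        raise NonConvergenceError("too few donors to fit the PMM regression")
    XtX = X_obs.T @ X_obs
    XtX.flat[:: p + 1] += 1e-8 * (np.trace(XtX) / p + 1.0)  # rank safety
    try:
        L = np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError as exc:
        raise NonConvergenceError("singular PMM design") from exc
    beta_hat = cho_solve((L, True), X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    rss = float(resid @ resid)
    sigma2_star = rss / rng.chisquare(n_obs - p) if rss > 0 else 0.0
    # M = sqrt(s2) L^{-T} satisfies M M' = s2 (X'X)^{-1}
    beta_star = beta_hat + np.sqrt(sigma2_star) * solve_triangular(
        L.T, rng.standard_normal(p), lower=False)

    donor_beta = beta_hat if matching_type == 1 else beta_star
    yhat_donor = X_obs @ donor_beta
    yhat_mis = X_mis @ beta_star

    if donor_mask is not None:
        if not donor_mask.any():
            raise NonConvergenceError("empty PMM donor pool")
        yhat_donor = yhat_donor[donor_mask]
        donor_values = y_obs[donor_mask]
    else:
        donor_values = y_obs
    k_eff = min(k, len(donor_values))
    if k_eff < k:
        warnings.warn(f"PMM donor pool smaller than k={k}; using k={k_eff}",
                      RuntimeWarning, stacklevel=2)

    pick = _nearest_donor_pick(yhat_donor, yhat_mis, k_eff, rng)
    return donor_values[pick]


def _nearest_donor_pick(yhat_donor: np.ndarray, yhat_mis: np.ndarray,
                        k: int, rng: np.random.Generator) -> np.ndarray:
    """Index of one uniformly drawn donor among each recipient's k nearest.

    In one dimension the k nearest donors form a contiguous window of the
    sorted donor predictions, so the search is a vectorized scan over the
    k+1 candidate windows around each recipient's insertion point. A tiny
    seeded jitter on the donor predictions breaks distance ties uniformly.
    """
    n_d = len(yhat_donor)
    spread = float(yhat_donor.max() - yhat_donor.min()) + 1.0
    jittered = yhat_donor + rng.random(n_d) * 1e-10 * spread
    order = np.argsort(jittered)
    d_sorted = jittered[order]
    pos = np.searchsorted(d_sorted, yhat_mis)
    starts = np.clip(pos[:, None] + np.arange(-k, 1)[None, :], 0, n_d - k)
    left = np.abs(d_sorted[starts] - yhat_mis[:, None])
    right = np.abs(d_sorted[starts + k - 1] - yhat_mis[:, None])
    best = np.maximum(left, right).argmin(axis=1)
    window_start = starts[np.arange(len(yhat_mis)), best]
    return order[window_start + rng.integers(0, k, len(yhat_mis))]


# ---------------------------------------------------------------------------
# chained-equation driver


def _initial_fill(ws: _Workspace, wave: int, mis_rows: np.ndarray,
                  stage: np.ndarray | None, rng: np.random.Generator) -> None:
    """Start each chain by drawing from the observed marginal of the wave
    (stage-2 cells draw from the observed ever-smoker marginal)."""
    col = ws.smoking[:, wave]
    obs_vals = col[~np.isnan(col)]
    if len(obs_vals) == 0:
        raise NonConvergenceError(f"wave {wave}: no observed values at all")
    for rows, support in _support_groups(mis_rows, stage):
        pool = obs_vals[np.isin(obs_vals, support)]
        if len(pool) == 0:
            pool = np.asarray(support, dtype=float)
        col[rows] = rng.choice(pool, size=len(rows))


def _support_groups(mis_rows: np.ndarray, stage: np.ndarray | None):
    """Split missing rows into (rows, allowed-support) groups."""
    if stage is None:
        yield mis_rows, (NEVER, EX, CURRENT)
        return
    s2 = mis_rows[stage[mis_rows] == STAGE2]
    s3 = mis_rows[stage[mis_rows] == STAGE3]
    if len(s2):
        yield s2, (EX, CURRENT)
    if len(s3):
        yield s3, (NEVER, EX, CURRENT)


def _impute_wave(ws: _Workspace, wave: int, obs_rows: np.ndarray,
                 mis_rows: np.ndarray, stage: np.ndarray | None,
                 spec: ImputationSpec, rng: np.random.Generator) -> None:
    X = ws.design(wave)
    y = ws.smoking[:, wave]
    y_obs, X_obs = y[obs_rows], X[obs_rows]
    for rows, support in _support_groups(mis_rows, stage):
        X_mis = X[rows]
        if spec.method == "pmm":
            mask = (np.isin(y_obs, support)
                    if len(support) < 3 else None)
            vals = impute_pmm(y_obs, X_obs, X_mis, spec.pmm_k,
                              spec.pmm_matching_type, rng, donor_mask=mask)
        else:
            if len(support) < 3:
                sub = np.isin(y_obs, support)
                if not sub.any():
                    raise NonConvergenceError(
                        f"wave {wave}: no observed ever-smokers for stage 2")
                fit_y, fit_X = y_obs[sub], X_obs[sub]
            else:
                fit_y, fit_X = y_obs, X_obs
            imputer = (impute_multinomial if spec.method == "multinomial"
                       else impute_ordinal)
            vals = imputer(fit_y, fit_X, X_mis, rng, categories=support)
        ws.smoking[rows, wave] = vals


def impute_fcs(masked_cohort: pd.DataFrame, spec: ImputationSpec,
               assignment: StageAssignment | None = None,
               rng: np.random.Generator | None = None) -> ImputedStack:
    """Run FCS (or two-fold FCS) and return the stack of m completed cohorts.

    With a :class:`StageAssignment`, stage-1 cells are pre-filled and each
    remaining cell is imputed on its allowed support. On any univariate
    fitting failure the stack is returned with ``converged=False`` and the
    partially imputed copies are discarded.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    work_cohort = masked_cohort
    if assignment is not None:
        work_cohort = apply_stage1(masked_cohort, assignment)

    smoking_cols = [f"m_smoking{j}" for j in range(6)]
    base_smoking = work_cohort[smoking_cols].to_numpy(float)
    missing = {w: np.nonzero(np.isnan(base_smoking[:, w]))[0]
               for w in MISSING_WAVES}
    observed = {w: np.nonzero(~np.isnan(base_smoking[:, w]))[0]
                for w in MISSING_WAVES}
    stages = ({w: assignment.stage_of(w) for w in MISSING_WAVES}
              if assignment is not None else {w: None for w in MISSING_WAVES})

    imputations: list[pd.DataFrame] = []
    reports: list[RestrictionReport] = []
    chain_rngs = rng.spawn(spec.m)
    for chain_rng in chain_rngs:
        ws = _Workspace(work_cohort, spec.two_fold)
        try:
            for wave in MISSING_WAVES:
                if len(missing[wave]):
                    _initial_fill(ws, wave, missing[wave], stages[wave],
                                  chain_rng)
            for _ in range(spec.n_cycles):
                for wave in MISSING_WAVES:
                    if len(missing[wave]):
                        _impute_wave(ws, wave, observed[wave], missing[wave],
                                     stages[wave], spec, chain_rng)
        except NonConvergenceError:
            return ImputedStack([], converged=False)
        completed = work_cohort.copy()
        for j in range(6):
            completed[f"m_smoking{j}"] = ws.smoking[:, j].astype(np.int64)
        imputations.append(completed)
        reports.append(audit_violations(completed, assignment))
    return ImputedStack(imputations, converged=True, reports=reports)


def impute_two_fold(masked_cohort: pd.DataFrame, spec: ImputationSpec,
                    assignment: StageAssignment | None = None,
                    rng: np.random.Generator | None = None) -> ImputedStack:
    """Two-fold FCS: each wave conditions only on its own and adjacent
    waves (plus time-independent covariates and wave-0 smoking), with the
    multinomial imputer."""
    spec2 = ImputationSpec(method="multinomial", m=spec.m,
                           n_cycles=spec.n_cycles, two_fold=True,
                           seed=spec.seed)
    return impute_fcs(masked_cohort, spec2, assignment, rng)
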