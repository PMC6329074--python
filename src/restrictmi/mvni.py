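"""Multivariate-normal imputation by data augmentation.

All imputation-model variables (time-independent covariates, wave ages,
depression, BMIz, and the smoking block for waves 0..5) are stacked into
one matrix assumed jointly normal. Missing entries — only the smoking cells
at waves 1..5 — are drawn by alternating

* **I-step**: each row's missing entries drawn from their conditional
  normal given the row's observed entries and the current (mu, Sigma);
* **P-step**: (mu, Sigma) drawn from the normal–inverse-Wishart posterior
  under a Jeffreys-style prior, with a ridge fallback when a draw is
  numerically singular.

Imputed smoking entries are real-valued and must be mapped back to the
categories {never, ex, current}. Two schemes are provided:

* **indicator + PDBR** — each wave encoded as two dummies (d1=[ex],
  d2=[current]); projected distance-based rounding returns the category
  whose indicator vertex is nearest in Euclidean distance. No attempt is
  made to preserve category proportions.
* **continuous + calibration** — each wave encoded as the code 0/1/2;
  imputed values are ranked and cut so that imputed category proportions
  match the observed proportions as closely as integer counts allow
  (largest-remainder apportionment).

Restriction adaptation: stage-1 cells are fixed before sampling (treated
as observed), stage-2 cells are rounded onto {ex, current} only (nearer of
the two vertices for PDBR; calibration within the observed ever-smoker
stratum), and stage-3 cells are rounded unrestricted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import CURRENT, EX, MISSING_WAVES, NEVER, TIME_INDEPENDENT
from .restriction import (
    STAGE2,
    STAGE3,
    RestrictionReport,
    StageAssignment,
    apply_stage1,
    audit_violations,
)
from .fcs import ImputedStack, NonConvergenceError


@dataclass
class MvniConfig:
    scheme: str = "indicator"       # or "continuous"
    m: int = 20
    n_burnin: int = 200
    n_between: int = 100
    ridge: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("indicator", "continuous"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.m < 2 or self.n_burnin < 0 or self.n_between < 1:
            raise ValueError("invalid sampler settings")


# ---------------------------------------------------------------------------
# encoding

_STATIC_COLS = (list(TIME_INDEPENDENT)
                + [f"scage{j}" for j in range(2, 7)]
                + [f"m_depression{j}" for j in range(6)]
                + [f"BMIz{j}" for j in range(2, 7)])


def encode(cohort: pd.DataFrame, scheme: str) -> tuple[np.ndarray, dict[int, list[int]]]:
    """Build the encoded data matrix and the column indices of each
    smoking wave's block (1 column continuous, 2 columns indicator)."""
    blocks = [cohort[_STATIC_COLS].to_numpy(float)]
    offset = blocks[0].shape[1]
    smoking_cols: dict[int, list[int]] = {}
    for wave in range(6):
        s = cohort[f"m_smoking{wave}"].to_numpy(float)
        if scheme == "continuous":
            blocks.append(s[:, None])
            smoking_cols[wave] = [offset]
            offset += 1
        else:
            d1 = np.where(np.isnan(s), np.nan, (s == EX).astype(float))
            d2 = np.where(np.isnan(s), np.nan, (s == CURRENT).astype(float))
            blocks.append(np.column_stack([d1, d2]))
            smoking_cols[wave] = [offset, offset + 1]
            offset += 2
    return np.column_stack(blocks), smoking_cols


def decode_complete(values: np.ndarray, scheme: str) -> np.ndarray:
    """Inverse of :func:`encode` for integer-valued (complete) data."""
    if scheme == "continuous":
        return values[:, 0].astype(np.int64)
    d1, d2 = values[:, 0], values[:, 1]
    return np.where(d2 > 0.5, CURRENT, np.where(d1 > 0.5, EX, NEVER))


# ---------------------------------------------------------------------------
# rounding schemes

_VERTICES = np.array([[0.0, 0.0],   # never
                      [1.0, 0.0],   # ex
                      [0.0, 1.0]])  # current


def pdbr_round(d1: np.ndarray, d2: np.ndarray,
               rng: np.random.Generator | None = None,
               allowed: tuple[int, ...] = (NEVER, EX, CURRENT)) -> np.ndarray:
    """Projected distance-based rounding: nearest indicator vertex.

    Equidistant inputs are resolved by a seeded uniform choice among the
    nearest vertices.
    """
    d1 = np.atleast_1d(np.asarray(d1, dtype=float))
    d2 = np.atleast_1d(np.asarray(d2, dtype=float))
    if not (np.all(np.isfinite(d1)) and np.all(np.isfinite(d2))):
        raise FloatingPointError("non-finite indicator values")
    pts = np.column_stack([d1, d2])
    cats = np.asarray(allowed)
    verts = _VERTICES[cats]
    dist = np.linalg.norm(pts[:, None, :] - verts[None, :, :], axis=2)
    is_min = np.isclose(dist, dist.min(axis=1, keepdims=True))
    n_ties = is_min.sum(axis=1)
    if (n_ties > 1).any():
        if rng is None:
            rng = np.random.default_rng(0)
        u = rng.random(len(pts))
        pick = (np.cumsum(is_min, axis=1) <= (u * n_ties)[:, None]).sum(axis=1)
    else:
        pick = dist.argmin(axis=1)
    return cats[pick]


def _apportion(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n items to the proportions."""
    quotas = proportions * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - counts))
        counts[order[:remainder]] += 1
    return counts


def calibration_round(imputed: np.ndarray, observed: np.ndarray,
                      categories: tuple[int, ...] = (NEVER, EX, CURRENT),
                      ) -> np.ndarray:
    """Rank-based calibration: cut the imputed continuous values so the
    imputed category proportions track the observed ones."""
    imputed = np.asarray(imputed, dtype=float)
    observed = np.asarray(observed, dtype=float)
    observed = observed[~np.isnan(observed)]
    if len(observed) == 0:
        raise NonConvergenceError("no observed values to calibrate against")
    cats = np.asarray(categories)
    props = np.array([(observed == c).mean() for c in cats])
    if props.sum() <= 0:
        raise NonConvergenceError("observed values outside the category set")
    props = props / props.sum()
    counts = _apportion(len(imputed), props)
    order = np.argsort(imputed, kind="stable")
    out = np.empty(len(imputed), dtype=np.int64)
    start = 0
    for cat, cnt in zip(cats, counts):
        out[order[start:start + cnt]] = cat
        start += cnt
    return out


# ---------------------------------------------------------------------------
# data-augmentation sampler


def _draw_posterior(data: np.ndarray, ridge: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n, d = data.shape
    xbar = data.mean(axis=0)
    centered = data - xbar
    S = centered.T @ centered
    df = n - 1
    if df <= d:
        raise NonConvergenceError("too few rows for the inverse-Wishart draw")
    scale_eye = ridge * np.trace(S) / d * np.eye(d)
    for attempt in range(3):
        try:
            sigma = stats.invwishart.rvs(df=df, scale=S + attempt * scale_eye,
                                         random_state=rng)
            np.linalg.cholesky(sigma)
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise NonConvergenceError("covariance draw not positive definite")
    mu = rng.multivariate_normal(xbar, sigma / n, method="cholesky")
    return mu, sigma


def _conditional_draw(rows: np.ndarray, mis_idx: np.ndarray, obs_idx: np.ndarray,
                      data: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                      rng: np.random.Generator) -> None:
    S_oo = sigma[np.ix_(obs_idx, obs_idx)]
    S_mo = sigma[np.ix_(mis_idx, obs_idx)]
    S_mm = sigma[np.ix_(mis_idx, mis_idx)]
    solve = np.linalg.solve(S_oo, S_mo.T)          # (n_obs, n_mis)
    cond_cov = S_mm - S_mo @ solve
    cond_cov = (cond_cov + cond_cov.T) / 2.0
    try:
        L = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(len(mis_idx)))
    except np.linalg.LinAlgError as exc:
        raise NonConvergenceError("conditional covariance singular") from exc
    resid = data[np.ix_(rows, obs_idx)] - mu[obs_idx]
    cond_mean = mu[mis_idx] + resid @ solve
    noise = rng.standard_normal((len(rows), len(mis_idx))) @ L.T
    data[np.ix_(rows, mis_idx)] = cond_mean + noise


def _augmentation_samples(Y: np.ndarray, config: MvniConfig,
                          rng: np.random.Generator) -> list[np.ndarray]:
    miss = np.isnan(Y)
    data = Y.copy()
    # start from marginal draws of each incomplete column
    for col in np.nonzero(miss.any(axis=0))[0]:
        obs = Y[~miss[:, col], col]
        data[miss[:, col], col] = rng.choice(obs, size=miss[:, col].sum())
    if not miss.any():
        return [data.copy() for _ in range(config.m)]

    # group rows by missingness pattern once
    pattern_ids = (miss @ (1 << np.arange(Y.shape[1], dtype=np.int64)))
    patterns = {}
    for pid in np.unique(pattern_ids):
        rows = np.nonzero(pattern_ids == pid)[0]
        mis_idx = np.nonzero(miss[rows[0]])[0]
        if len(mis_idx):
            obs_idx = np.nonzero(~miss[rows[0]])[0]
            patterns[pid] = (rows, mis_idx, obs_idx)

    saved = []
    total = config.n_burnin + config.n_between * config.m
    for it in range(1, total + 1):
        mu, sigma = _draw_posterior(data, config.ridge, rng)
        for rows, mis_idx, obs_idx in patterns.values():
            _conditional_draw(rows, mis_idx, obs_idx, data, mu, sigma, rng)
        if it > config.n_burnin and (it - config.n_burnin) % config.n_between == 0:
            saved.append(data.copy())
    return saved


def _round_wave(encoded: np.ndarray, wave_cols: list[int], base: np.ndarray,
                stage: np.ndarray | None, mis_rows: np.ndarray,
                scheme: str, rng: np.random.Generator) -> np.ndarray:
    """Round one wave's imputed entries back to categories."""
    observed_codes = base[~np.isnan(base)]
    out = base.copy()
    groups = ([(mis_rows, (NEVER, EX, CURRENT))] if stage is None else
              [(mis_rows[stage[mis_rows] == STAGE2], (EX, CURRENT)),
               (mis_rows[stage[mis_rows] == STAGE3], (NEVER, EX, CURRENT))])
    for rows, allowed in groups:
        if len(rows) == 0:
            continue
        if scheme == "indicator":
            out[rows] = pdbr_round(encoded[rows, wave_cols[0]],
                                   encoded[rows, wave_cols[1]],
                                   rng, allowed=allowed)
        else:
            ref = observed_codes[np.isin(observed_codes, allowed)]
            if len(ref) == 0:
                raise NonConvergenceError(
                    "no observed values in the allowed stratum to calibrate")
            out[rows] = calibration_round(encoded[rows, wave_cols[0]], ref,
                                          categories=allowed)
    return out


def impute_mvni(masked_cohort: pd.DataFrame, config: MvniConfig,
                assignment: StageAssignment | None = None,
                rng: np.random.Generator | None = None) -> ImputedStack:
    """Joint-normal imputation of the smoking waves, rounded per scheme."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    work = masked_cohort if assignment is None else apply_stage1(
        masked_cohort, assignment)
    Y, smoking_cols = encode(work, config.scheme)
    base_smoking = work[[f"m_smoking{j}" for j in range(6)]].to_numpy(float)
    try:
        samples = _augmentation_samples(Y, config, rng)
    except NonConvergenceError:
        return ImputedStack([], converged=False)

    imputations, reports = [], []
    for sample in samples:
        completed = work.copy()
        ok = True
        for wave in MISSING_WAVES:
            base = base_smoking[:, wave]
            mis_rows = np.nonzero(np.isnan(base))[0]
            if len(mis_rows) == 0:
                completed[f"m_smoking{wave}"] = base.astype(np.int64)
                continue
            stage = assignment.stage_of(wave) if assignment is not None else None
            try:
                rounded = _round_wave(sample, smoking_cols[wave], base, stage,
                                      mis_rows, config.scheme, rng)
            except NonConvergenceError:
                ok = False
                break
            completed[f"m_smoking{wave}"] = rounded.astype(np.int64)
        if not ok:
            return ImputedStack([], converged=False)
        completed["m_smoking0"] = base_smoking[:, 0].astype(np.int64)
        completed["m_smoking6"] = completed["m_smoking6"].astype(np.int64)
        imputations.append(completed)
        reports.append(audit_violations(completed, assignment))
    return ImputedStack(imputations, converged=True, reports=reports)
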