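"""Target analysis model, CCA/ACA variants, and Rubin pooling.

The analysis of interest is a random-intercept linear mixed model of BMIz
at waves 2..6 on the previous wave's smoking category (never-smoker as
reference) and the adjustment covariates:

    BMIz_ij = (b0 + b_0i) + b_ex[smoke_{j-1}=1] + b_cur[smoke_{j-1}=2]
              + b_scage scage_ij + ... + e_ij,
    b_0i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2).

The fit uses profiled REML specialized to the random-intercept structure:
for a fixed variance ratio gamma = sigma_b^2/sigma_e^2 the GLS solution
and the profiled residual variance are closed-form (group-wise Woodbury),
leaving a one-dimensional optimization over log gamma. This is exact for
the model class and orders of magnitude faster than a general mixed-model
solver; tests cross-check coefficients and standard errors against
statsmodels MixedLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import CURRENT, EX, MISSING_WAVES, TIME_INDEPENDENT

#: fixed-effect design, in order
FIXED_EFFECTS = ("intercept", "smoking_ex", "smoking_cur", "scage",
                 "breastfed", "m_age", "m_education", "birthweight", "sex",
                 "ses")


class AnalysisError(RuntimeError):
    pass


@dataclass
class AnalysisResult:
    params: pd.Series
    bse: pd.Series
    df_resid: float
    sigma2_b: float
    sigma2_e: float
    n_subjects_used: int
    n_rows_used: int
    converged: bool = True

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})


def to_long(cohort: pd.DataFrame) -> pd.DataFrame:
    """Wide cohort to analysis rows (subject x outcome wave 2..6), with the
    previous wave's smoking category as the lagged exposure."""
    frames = []
    for j in range(2, 7):
        frame = pd.DataFrame({
            "subject": cohort.index.to_numpy(),
            "wave": j,
            "BMIz": cohort[f"BMIz{j}"].to_numpy(float),
            "smoking_lag": cohort[f"m_smoking{j-1}"].to_numpy(float),
            "scage": cohort[f"scage{j}"].to_numpy(float),
        })
        for c in TIME_INDEPENDENT:
            frame[c] = cohort[c].to_numpy(float)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _design(long_df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = long_df["BMIz"].to_numpy(float)
    s = long_df["smoking_lag"].to_numpy(float)
    X = np.column_stack([
        np.ones(len(long_df)),
        (s == EX).astype(float),
        (s == CURRENT).astype(float),
        long_df["scage"].to_numpy(float),
        long_df["breastfed"].to_numpy(float),
        long_df["m_age"].to_numpy(float),
        long_df["m_education"].to_numpy(float),
        long_df["birthweight"].to_numpy(float),
        long_df["sex"].to_numpy(float),
        long_df["ses"].to_numpy(float),
    ])
    groups = pd.factorize(long_df["subject"])[0]
    return y, X, groups


def _reml_profile(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Closed-form pieces of the profiled REML criterion."""
    n, p = X.shape
    n_groups = groups.max() + 1
    ni = np.bincount(groups, minlength=n_groups).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Sx = np.zeros((n_groups, p))
    np.add.at(Sx, groups, X)
    Sy = np.bincount(groups, weights=y, minlength=n_groups)

    def pieces(gamma: float):
        c = gamma / (1.0 + gamma * ni)
        A = XtX - (Sx * c[:, None]).T @ Sx
        b = Xty - Sx.T @ (c * Sy)
        try:
            cho = np.linalg.cholesky(A)
        except np.linalg.LinAlgError as exc:
            raise AnalysisError("singular fixed-effect design") from exc
        beta = np.linalg.solve(A, b)
        yVy = yty - float((c * Sy * Sy).sum())
        rVr = max(yVy - 2.0 * beta @ b + beta @ (A @ beta), 1e-300)
        sigma2 = rVr / (n - p)
        logdet_V = float(np.log1p(gamma * ni).sum())
        logdet_A = 2.0 * float(np.log(np.diag(cho)).sum())
        crit = (n - p) * np.log(sigma2) + logdet_V + logdet_A
        return crit, beta, sigma2, A

    return pieces


def fit_lmm(long_df: pd.DataFrame) -> AnalysisResult:
    """REML fit of the random-intercept model on long-format analysis rows.

    Rows with a missing lagged exposure or outcome must be removed by the
    caller (see :func:`aca_fit`). A variance-ratio estimate at the lower
    boundary degrades gracefully to the independence (OLS) fit.
    """
    if len(long_df) == 0:
        raise AnalysisError("empty analysis set")
    if long_df[["BMIz", "smoking_lag"]].isna().any().any():
        raise AnalysisError("analysis rows contain missing values")
    y, X, groups = _design(long_df)
    n, p = X.shape
    if n <= p:
        raise AnalysisError("not enough rows to fit the analysis model")
    pieces = _reml_profile(y, X, groups)

    def objective(log_gamma: float) -> float:
        return pieces(np.exp(log_gamma))[0]

    opt = optimize.minimize_scalar(objective, bounds=(-12.0, 12.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    gamma = float(np.exp(opt.x))
    crit, beta, sigma2, A = pieces(gamma)
    crit0, beta0, sigma2_0, A0 = pieces(0.0)
    if crit0 <= crit:   # boundary solution: no between-subject variance
        gamma, beta, sigma2, A = 0.0, beta0, sigma2_0, A0
    cov = sigma2 * np.linalg.inv(A)
    params = pd.Series(beta, index=FIXED_EFFECTS)
    bse = pd.Series(np.sqrt(np.diag(cov)), index=FIXED_EFFECTS)
    return AnalysisResult(
        params=params, bse=bse, df_resid=float(n - p),
        sigma2_b=gamma * sigma2, sigma2_e=sigma2,
        n_subjects_used=int(groups.max() + 1), n_rows_used=int(n),
        converged=bool(opt.success))


def fit_cohort(cohort: pd.DataFrame) -> AnalysisResult:
    """Fit the analysis model to a complete (or completed) cohort."""
    return fit_lmm(to_long(cohort))


def cca_fit(masked_cohort: pd.DataFrame) -> AnalysisResult:
    """Complete case analysis: drop every subject with any missing smoking
    value at waves 1..5, then fit."""
    smoking = masked_cohort[[f"m_smoking{j}" for j in MISSING_WAVES]]
    keep = ~smoking.isna().any(axis=1)
    if not keep.any():
        raise AnalysisError("no complete cases remain")
    return fit_lmm(to_long(masked_cohort.loc[keep]))


def aca_fit(masked_cohort: pd.DataFrame) -> AnalysisResult:
    """Available case analysis: drop only the analysis rows whose lagged
    smoking exposure is missing, then fit."""
    long_df = to_long(masked_cohort)
    long_df = long_df[long_df["smoking_lag"].notna()]
    if len(long_df) == 0:
        raise AnalysisError("no available rows remain")
    return fit_lmm(long_df)


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass
class PooledEstimate:
    qbar: float
    within: float      # W: mean squared SE
    between: float     # B: between-imputation variance of the estimates
    total: float       # T = W + (1 + 1/m) B
    df: float
    ci_lower: float
    ci_upper: float
    m_used: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))


def rubin_pool(estimates: np.ndarray, ses: np.ndarray,
               complete_df: float = np.inf) -> PooledEstimate:
    """Combine m point estimates and standard errors by Rubin's rules.

    df follows the original large-sample formula
    (m-1)(1 + W/((1+1/m)B))^2; when B = 0 the complete-data df applies.
    """
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    m = len(estimates)
    if m < 2:
        raise AnalysisError("Rubin pooling needs at least 2 imputations")
    qbar = float(estimates.mean())
    W = float((ses ** 2).mean())
    B = float(estimates.var(ddof=1))
    if B <= 1e-12 * max(W, np.finfo(float).tiny):
        B = 0.0   # numerically identical estimates
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
    else:
        df = complete_df
    q = (stats.t.ppf(0.975, df) if np.isfinite(df)
         else stats.norm.ppf(0.975))
    half = q * np.sqrt(T)
    return PooledEstimate(qbar, W, B, T, float(df),
                          qbar - half, qbar + half, m)


def pool_results(results: list[AnalysisResult],
                 parameters: tuple[str, ...] = ("smoking_ex", "smoking_cur"),
                 ) -> dict[str, PooledEstimate]:
    """Pool each requested parameter over a list of per-imputation fits."""
    if len(results) < 2:
        raise AnalysisError("Rubin pooling needs at least 2 imputations")
    pooled = {}
    complete_df = results[0].df_resid
    for name in parameters:
        est = np.array([r.params[name] for r in results])
        se = np.array([r.bse[name] for r in results])
        pooled[name] = rubin_pool(est, se, complete_df=complete_df)
    return pooled
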