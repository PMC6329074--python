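"""Calibrated MCAR/MAR missingness for smoking waves 1..5.

Two logistic mechanisms act in sequence on each cohort:

* **Model A (dropout)** — once a subject's smoking value goes missing at
  wave j, it stays missing at every later wave (monotone attrition).
* **Model B (intermittent)** — independent per-wave gaps among the cells
  Model A left observed, so later waves can be observed again.

Under MAR both models' logits depend on maternal depression at the same
wave and BMIz at the following wave — both always observed, so missingness
is independent of the unobserved smoking values given observed data. MCAR
uses the same two-model machinery with zero slopes.

The per-wave intercepts are not free parameters: they are solved by
root-finding so that the achieved per-wave marginal missingness matches a
configured schedule whose mean is the overall target (45% realistic, 65%
extreme). Calibration propagates dropout deterministically through
survival weights, so it needs no missingness draws of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .params import ConfigurationError, MISSING_WAVES

Mechanism = Literal["MCAR", "MAR_weak", "MAR_strong"]

# Odds ratios of the two missingness predictors (depression at wave j,
# BMIz at wave j+1), per mechanism strength and model.
WEAK_MAR_ODDS = {"model_A": (1.67, 1.64), "model_B": (1.61, 1.58)}
STRONG_MAR_ODDS = {"model_A": (2.80, 2.60), "model_B": (2.70, 2.50)}


def strong_from_weak(weak_odds: dict[str, tuple[float, float]]) -> dict:
    """Strong-MAR odds from weak-MAR odds by doubling each log-odds."""
    return {model: tuple(np.exp(2.0 * np.log(np.asarray(ors))))
            for model, ors in weak_odds.items()}


def default_wave_targets(overall: float, spread: float = 0.10) -> tuple[float, ...]:
    """Linearly increasing per-wave marginal targets averaging ``overall``.

    Longitudinal attrition accumulates, so later waves miss more; the
    default spreads the five wave targets symmetrically around the overall
    proportion in steps of ``spread``.
    """
    targets = tuple(overall + spread * k for k in (-2, -1, 0, 1, 2))
    if not all(0.0 < t < 1.0 for t in targets):
        raise ConfigurationError(
            f"wave targets {targets} fall outside (0,1); reduce the spread")
    return targets


@dataclass
class MissingnessConfig:
    mechanism: Mechanism = "MAR_weak"
    overall_target: float = 0.45
    wave_targets: tuple[float, ...] | None = None
    dropout_share: float = 0.60     # fraction of each wave's marginal target
    #                                 attributable to Model A dropout
    model_A_odds: tuple[float, float] | None = None  # (depression, BMIz_{j+1})
    model_B_odds: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.overall_target < 1.0:
            raise ConfigurationError("overall_target must lie in (0,1)")
        if not 0.0 < self.dropout_share < 1.0:
            raise ConfigurationError("dropout_share must lie in (0,1)")
        if self.wave_targets is None:
            self.wave_targets = default_wave_targets(self.overall_target)
        self.wave_targets = tuple(float(t) for t in self.wave_targets)
        if len(self.wave_targets) != 5:
            raise ConfigurationError("wave_targets must cover waves 1..5")
        if not np.isclose(np.mean(self.wave_targets), self.overall_target,
                          atol=1e-9):
            raise ConfigurationError(
                "wave_targets must average to overall_target")
        if self.model_A_odds is None or self.model_B_odds is None:
            if self.mechanism == "MCAR":
                odds = {"model_A": (1.0, 1.0), "model_B": (1.0, 1.0)}
            elif self.mechanism == "MAR_weak":
                odds = WEAK_MAR_ODDS
            elif self.mechanism == "MAR_strong":
                odds = STRONG_MAR_ODDS
            else:
                raise ConfigurationError(f"unknown mechanism {self.mechanism}")
            self.model_A_odds = self.model_A_odds or odds["model_A"]
            self.model_B_odds = self.model_B_odds or odds["model_B"]
        for ors in (self.model_A_odds, self.model_B_odds):
            if any(o <= 0 for o in ors):
                raise ConfigurationError("odds ratios must be positive")


@dataclass
class CalibratedIntercepts:
    """Per-wave intercepts for the two mechanisms plus their hazard targets."""
    nu0: tuple[float, ...]       # Model A, waves 1..5
    omega0: tuple[float, ...]    # Model B, waves 1..5
    dropout_marginals: tuple[float, ...]
    intermittent_rates: tuple[float, ...]


def _mechanism_features(cohort: pd.DataFrame, wave: int) -> tuple[np.ndarray, np.ndarray]:
    dep = cohort[f"m_depression{wave}"].to_numpy(dtype=float)
    bmiz = cohort[f"BMIz{wave + 1}"].to_numpy(dtype=float)
    return dep, bmiz


def _solve_intercept(eta: np.ndarray, weights: np.ndarray, target: float) -> float:
    """Intercept c with weighted mean expit(c + eta) equal to target.

    Monotone in c, so bracketed root-finding always succeeds for targets
    strictly inside (0,1).
    """
    wsum = weights.sum()

    def gap(c: float) -> float:
        return float((weights * expit(c + eta)).sum() / wsum - target)

    lo, hi = logit(target) - eta.max(), logit(target) - eta.min()
    if lo == hi:
        return lo
    return brentq(gap, lo - 1e-9, hi + 1e-9, xtol=1e-12)


def calibrate_intercepts(cohorts: Iterable[pd.DataFrame],
                         config: MissingnessConfig) -> CalibratedIntercepts:
    """Solve the per-wave intercepts against a calibration sample.

    Model A is calibrated sequentially wave 1 -> 5 because dropout
    accumulates: the wave-j incident hazard applies only to subjects still
    observed, tracked by per-subject survival probabilities rather than by
    drawing masks. Model B is then calibrated to hit the intermittent rate
    among cells Model A leaves observed.
    """
    sample = pd.concat(list(cohorts), ignore_index=True)
    targets = np.asarray(config.wave_targets)
    dropout_marg = config.dropout_share * targets
    if np.any(np.diff(dropout_marg) < 0):
        raise ConfigurationError(
            "dropout marginals must be non-decreasing across waves")
    intermittent = (targets - dropout_marg) / (1.0 - dropout_marg)

    log_nu = np.log(config.model_A_odds)
    log_om = np.log(config.model_B_odds)

    nu0, omega0 = [], []
    survive = np.ones(len(sample))   # P(not yet dropped) per subject
    prev_dropout = 0.0
    for idx, wave in enumerate(MISSING_WAVES):
        dep, bmiz = _mechanism_features(sample, wave)
        eta_A = log_nu[0] * dep + log_nu[1] * bmiz
        hazard = (dropout_marg[idx] - prev_dropout) / (1.0 - prev_dropout)
        if not 0.0 < hazard < 1.0:
            raise ConfigurationError(
                f"wave {wave}: incident dropout hazard {hazard:.3f} is "
                "unattainable given earlier waves")
        c = _solve_intercept(eta_A, survive, hazard)
        nu0.append(c)
        p_drop = expit(c + eta_A)

        eta_B = log_om[0] * dep + log_om[1] * bmiz
        w_obs = survive * (1.0 - p_drop)
        omega0.append(_solve_intercept(eta_B, w_obs, intermittent[idx]))

        survive = w_obs
        prev_dropout = dropout_marg[idx]

    return CalibratedIntercepts(tuple(nu0), tuple(omega0),
                                tuple(dropout_marg), tuple(intermittent))


OBSERVED, DROPOUT, INTERMITTENT = 0, 1, 2
SOURCE_LABELS = {OBSERVED: "observed", DROPOUT: "dropout",
                 INTERMITTENT: "intermittent"}


@dataclass
class MissingnessMask:
    """Missingness over (subject x wave 1..5) with provenance per cell."""
    R: np.ndarray          # bool (n, 5); True = missing
    source: np.ndarray     # int codes, same shape

    def overall_proportion(self) -> float:
        return float(self.R.mean())

    def wave_proportions(self) -> np.ndarray:
        return self.R.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        n = self.R.shape[0]
        rows = []
        for idx, wave in enumerate(MISSING_WAVES):
            rows.append(pd.DataFrame({
                "subject_id": np.arange(n), "wave": wave,
                "R": self.R[:, idx].astype(int),
                "source": [SOURCE_LABELS[s] for s in self.source[:, idx]],
            }))
        return pd.concat(rows, ignore_index=True)


def apply_model_A(cohort: pd.DataFrame,
                  intercepts: CalibratedIntercepts,
                  config: MissingnessConfig,
                  rng: np.random.Generator) -> MissingnessMask:
    """Monotone dropout: once missing, missing at every later wave."""
    n = len(cohort)
    log_nu = np.log(config.model_A_odds)
    R = np.zeros((n, 5), dtype=bool)
    source = np.zeros((n, 5), dtype=np.int64)
    dropped = np.zeros(n, dtype=bool)
    for idx, wave in enumerate(MISSING_WAVES):
        dep, bmiz = _mechanism_features(cohort, wave)
        p = expit(intercepts.nu0[idx] + log_nu[0] * dep + log_nu[1] * bmiz)
        new_drop = ~dropped & (rng.random(n) < p)
        dropped |= new_drop
        R[:, idx] = dropped
        source[dropped, idx] = DROPOUT
    return MissingnessMask(R, source)


def apply_model_B(cohort: pd.DataFrame,
                  mask: MissingnessMask,
                  intercepts: CalibratedIntercepts,
                  config: MissingnessConfig,
                  rng: np.random.Generator) -> MissingnessMask:
    """Intermittent gaps among the cells still observed after Model A."""
    n = len(cohort)
    log_om = np.log(config.model_B_odds)
    R = mask.R.copy()
    source = mask.source.copy()
    for idx, wave in enumerate(MISSING_WAVES):
        still_obs = ~R[:, idx]
        if not still_obs.any():
            continue
        dep, bmiz = _mechanism_features(cohort, wave)
        p = expit(intercepts.omega0[idx] + log_om[0] * dep + log_om[1] * bmiz)
        hit = still_obs & (rng.random(n) < p)
        R[hit, idx] = True
        source[hit, idx] = INTERMITTENT
    return MissingnessMask(R, source)


def impose_missingness(cohort: pd.DataFrame,
                       intercepts: CalibratedIntercepts,
                       config: MissingnessConfig,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, MissingnessMask]:
    """Apply both mechanisms and blank the masked smoking cells."""
    mask = apply_model_A(cohort, intercepts, config, rng)
    mask = apply_model_B(cohort, mask, intercepts, config, rng)
    masked = cohort.copy()
    for idx, wave in enumerate(MISSING_WAVES):
        col = masked[f"m_smoking{wave}"].astype(float).to_numpy()
        col[mask.R[:, idx]] = np.nan
        masked[f"m_smoking{wave}"] = col
    return masked, mask
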