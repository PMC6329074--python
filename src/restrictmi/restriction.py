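"""Three-stage semi-deterministic restriction procedure.

A forward-only categorical trajectory (never=0, ex=1, current=2; ever
states cannot return to never) partially observed over waves 0..5 lets the
observed values logically constrain each missing cell:

* **Stage 1** — a later wave is observed "never": every earlier missing
  cell must be "never" and is filled deterministically.
* **Stage 2** — an earlier wave is observed "ex" or "current": the missing
  cell can only be ex or current; it is imputed stochastically on {1,2}.
* **Stage 3** — neither constraint applies: imputed on the full {0,1,2}
  support. Stage-3 draws can still produce implausible ever->never
  transitions; those are accepted and audited rather than resampled.

Classification is purely deterministic and order-invariant; the engines
consume the resulting cell assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CURRENT, EX, NEVER

#: waves inspected when classifying (wave 6 is generated but unanalyzed and
#: excluded by default; pass ``waves=range(7)`` to include it)
CLASSIFY_WAVES = tuple(range(6))

STAGE1, STAGE2, STAGE3 = 1, 2, 3
ALLOWED = {STAGE1: frozenset({NEVER}),
           STAGE2: frozenset({EX, CURRENT}),
           STAGE3: frozenset({NEVER, EX, CURRENT})}


class InconsistentTrajectoryError(ValueError):
    """Observed values themselves violate the forward-only restriction."""


@dataclass
class StageAssignment:
    """Stage per missing cell: 0 where observed, else 1/2/3."""
    stage: np.ndarray   # int (n_subjects, n_waves)
    waves: tuple[int, ...]

    def counts(self) -> dict[int, int]:
        return {s: int((self.stage == s).sum()) for s in (STAGE1, STAGE2, STAGE3)}

    def stage_of(self, wave: int) -> np.ndarray:
        return self.stage[:, self.waves.index(wave)]


def classify_missing_cells(smoking: np.ndarray | pd.DataFrame,
                           waves: tuple[int, ...] = CLASSIFY_WAVES) -> StageAssignment:
    """Assign each missing cell to a restriction stage.

    ``smoking`` holds category codes over the classification waves with NaN
    for missing cells (columns ordered by wave). Raises
    :class:`InconsistentTrajectoryError` when the observed values alone
    contain an ever->never step.
    """
    S = np.asarray(smoking, dtype=float)
    if S.ndim == 1:
        S = S[None, :]
    if S.shape[1] != len(waves):
        raise ValueError("column count must match the classification waves")
    observed = ~np.isnan(S)

    # observed consistency: any observed ever followed by an observed never
    ever_seen = np.zeros(S.shape[0], dtype=bool)
    for j in range(S.shape[1]):
        obs_j = observed[:, j]
        if (ever_seen & obs_j & (S[:, j] == NEVER)).any():
            bad = np.nonzero(ever_seen & obs_j & (S[:, j] == NEVER))[0]
            raise InconsistentTrajectoryError(
                f"observed never-smoker after an observed ever-smoker "
                f"(subject index {bad[0]}, wave {waves[j]})")
        ever_seen |= obs_j & (S[:, j] != NEVER)

    obs_never = observed & (S == NEVER)
    obs_ever = observed & ~np.isnan(S) & (S != NEVER)
    # later observed never (strictly after j) / earlier observed ever
    later_never = np.zeros_like(obs_never)
    later_never[:, :-1] = np.flip(
        np.maximum.accumulate(np.flip(obs_never[:, 1:], axis=1), axis=1), axis=1)
    earlier_ever = np.zeros_like(obs_ever)
    earlier_ever[:, 1:] = np.maximum.accumulate(obs_ever[:, :-1], axis=1)

    stage = np.zeros(S.shape, dtype=np.int64)
    missing = ~observed
    stage[missing & later_never] = STAGE1
    stage[missing & ~later_never & earlier_ever] = STAGE2
    stage[missing & ~later_never & ~earlier_ever] = STAGE3
    return StageAssignment(stage=stage, waves=tuple(waves))


def assignment_for_cohort(masked_cohort: pd.DataFrame,
                          waves: tuple[int, ...] = CLASSIFY_WAVES) -> StageAssignment:
    cols = [f"m_smoking{j}" for j in waves]
    return classify_missing_cells(masked_cohort[cols].to_numpy(dtype=float), waves)


def apply_stage1(masked_cohort: pd.DataFrame,
                 assignment: StageAssignment) -> pd.DataFrame:
    """Deterministically backfill stage-1 cells with "never" (identical
    across all imputations)."""
    out = masked_cohort.copy()
    for j, wave in enumerate(assignment.waves):
        col = f"m_smoking{wave}"
        if col not in out.columns:
            continue
        fill = assignment.stage[:, j] == STAGE1
        if fill.any():
            vals = out[col].to_numpy(dtype=float, copy=True)
            vals[fill] = NEVER
            out[col] = vals
    return out


@dataclass
class RestrictionReport:
    n_stage1: int
    n_stage2: int
    n_stage3: int
    n_violations: int

    @property
    def violation_rate(self) -> float:
        n_cells = self.n_stage1 + self.n_stage2 + self.n_stage3
        return self.n_violations / n_cells if n_cells else 0.0


def count_violations(smoking: np.ndarray) -> int:
    """Number of adjacent ever->never transitions across the given waves."""
    S = np.asarray(smoking, dtype=float)
    return int(((S[:, :-1] != NEVER) & (S[:, 1:] == NEVER)).sum())


def audit_violations(imputed_cohort: pd.DataFrame,
                     assignment: StageAssignment | None = None,
                     waves: tuple[int, ...] = tuple(range(7))) -> RestrictionReport:
    """Count implausible ever->never transitions in a completed cohort."""
    cols = [f"m_smoking{j}" for j in waves if f"m_smoking{j}" in imputed_cohort]
    n_viol = count_violations(imputed_cohort[cols].to_numpy(dtype=float))
    counts = assignment.counts() if assignment is not None else {1: 0, 2: 0, 3: 0}
    return RestrictionReport(counts[STAGE1], counts[STAGE2], counts[STAGE3],
                             n_viol)
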