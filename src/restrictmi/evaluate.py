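"""Scenario orchestration and simulation performance metrics.

Runs the full factorial of missingness mechanism (MCAR, weak MAR, strong
MAR) x overall proportion (45%, 65%) x handling method (CCA, ACA, the FCS
and MVNI engines with and without the restriction procedure), repeats over
freshly simulated cohorts, and summarizes bias, precision, coverage and
non-convergence per method and parameter.

Metrics over R converged replicates with truth beta:
    bias   = mean(est) - beta          relative bias % = 100 bias / beta
    empSE  = SD(est)                   modSE = mean(SE)
    coverage % of 95% CIs containing beta
    MSE    = mean((est - beta)^2)      MC error of bias = empSE / sqrt(R)

Replicates on which a method's imputation or analysis fails are excluded
from that method's summaries and counted in its non-convergence rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import analysis, fcs, missingness, mvni, restriction, simulate
from .params import SimulationParams

PARAMETERS = ("smoking_ex", "smoking_cur")

MI_METHODS = ("fcs-multinomial", "fcs-ordinal", "fcs-pmm5", "fcs-pmm10",
              "twofold-fcs", "mvni-pdbr", "mvni-calibration")
ALL_METHODS = ("CCA", "ACA") + MI_METHODS


@dataclass
class ScenarioGrid:
    mechanisms: tuple[str, ...] = ("MCAR", "MAR_weak", "MAR_strong")
    proportions: tuple[float, ...] = (0.45, 0.65)
    methods: tuple[str, ...] = ALL_METHODS
    restriction_status: tuple[bool, ...] = (False, True)
    n_reps: int = 100
    m: int = 20
    base_seed: int = 0

    def cells(self):
        for mech in self.mechanisms:
            for prop in self.proportions:
                yield mech, prop


@dataclass
class MethodOutcome:
    """One method's result on one replicate."""
    estimates: dict[str, float] | None
    ses: dict[str, float] | None
    cis: dict[str, tuple[float, float]] | None
    converged: bool
    n_violations: float = np.nan   # mean over imputations; 0 for CCA/ACA


def _outcome_from_result(res: analysis.AnalysisResult) -> MethodOutcome:
    ci = res.conf_int()
    return MethodOutcome(
        estimates={p: float(res.params[p]) for p in PARAMETERS},
        ses={p: float(res.bse[p]) for p in PARAMETERS},
        cis={p: (float(ci.loc[p, "lower"]), float(ci.loc[p, "upper"]))
             for p in PARAMETERS},
        converged=res.converged, n_violations=0.0)


def _outcome_from_stack(stack: fcs.ImputedStack) -> MethodOutcome:
    if not stack.converged:
        return MethodOutcome(None, None, None, converged=False)
    fits = [analysis.fit_cohort(c) for c in stack.imputations]
    pooled = analysis.pool_results(fits, PARAMETERS)
    viol = float(np.mean([r.n_violations for r in stack.reports]))
    return MethodOutcome(
        estimates={p: pooled[p].qbar for p in PARAMETERS},
        ses={p: pooled[p].se for p in PARAMETERS},
        cis={p: (pooled[p].ci_lower, pooled[p].ci_upper) for p in PARAMETERS},
        converged=True, n_violations=viol)


def run_method(method: str, masked_cohort: pd.DataFrame,
               restricted: bool, m: int,
               rng: np.random.Generator) -> MethodOutcome:
    """Apply one missing-data handling method to one masked cohort."""
    if method in ("CCA", "ACA"):
        try:
            res = (analysis.cca_fit if method == "CCA" else
                   analysis.aca_fit)(masked_cohort)
        except analysis.AnalysisError:
            return MethodOutcome(None, None, None, converged=False)
        return _outcome_from_result(res)

    assignment = (restriction.assignment_for_cohort(masked_cohort)
                  if restricted else None)
    if method.startswith("fcs-") or method == "twofold-fcs":
        if method == "twofold-fcs":
            spec = fcs.ImputationSpec(method="multinomial", m=m,
                                      two_fold=True)
        elif method == "fcs-multinomial":
            spec = fcs.ImputationSpec(method="multinomial", m=m)
        elif method == "fcs-ordinal":
            spec = fcs.ImputationSpec(method="ordinal", m=m)
        elif method in ("fcs-pmm5", "fcs-pmm10"):
            spec = fcs.ImputationSpec(method="pmm",
                                      pmm_k=5 if method.endswith("5") else 10,
                                      m=m)
        else:
            raise ValueError(f"unknown method {method!r}")
        stack = fcs.impute_fcs(masked_cohort, spec, assignment, rng)
    elif method.startswith("mvni-"):
        scheme = "indicator" if method == "mvni-pdbr" else "continuous"
        config = mvni.MvniConfig(scheme=scheme, m=m)
        stack = mvni.impute_mvni(masked_cohort, config, assignment, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _outcome_from_stack(stack)


def compute_metrics(estimates: Sequence[float], ses: Sequence[float],
                    cis: Sequence[tuple[float, float]], truth: float,
                    n_attempted: int | None = None) -> dict[str, float]:
    """Performance measures over the converged replicates of one cell."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    n = len(est)
    if n < 2:
        raise ValueError("need at least 2 converged replicates")
    bias = float(est.mean() - truth)
    emp_se = float(est.std(ddof=1))
    covered = np.array([lo <= truth <= hi for lo, hi in cis])
    out = {
        "bias": bias,
        "relative_bias_pct": 100.0 * bias / truth if truth != 0 else np.nan,
        "empirical_se": emp_se,
        "model_se": float(se.mean()),
        "coverage_pct": 100.0 * float(covered.mean()),
        "mse": float(((est - truth) ** 2).mean()),
        "mc_error_bias": emp_se / np.sqrt(n),
        "n_converged": float(n),
    }
    if n_attempted:
        out["nonconvergence_pct"] = 100.0 * (1.0 - n / n_attempted)
    return out


def run_scenario(mechanism: str, proportion: float,
                 methods: Sequence[str],
                 params: SimulationParams,
                 n_reps: int, m: int, seed: int,
                 restricted: Iterable[bool] = (False, True),
                 n_calibration_cohorts: int = 10,
                 ) -> pd.DataFrame:
    """Run one mechanism x proportion cell and return the performance table.

    Intercepts are calibrated once on an independent sample of cohorts,
    then each replicate simulates a cohort, imposes missingness, runs every
    requested method/restriction combination, and records pooled estimates.
    """
    config = missingness.MissingnessConfig(mechanism=mechanism,
                                           overall_target=proportion)
    master = np.random.SeedSequence(seed)
    calib_ss, rep_ss = master.spawn(2)
    calib_rngs = [np.random.default_rng(s)
                  for s in calib_ss.spawn(n_calibration_cohorts)]
    intercepts = missingness.calibrate_intercepts(
        (simulate.simulate_cohort(params, r) for r in calib_rngs), config)

    combos = [(meth, rest) for meth in methods
              for rest in ((False,) if meth in ("CCA", "ACA")
                           else tuple(restricted))]
    records: dict[tuple, list[MethodOutcome]] = {c: [] for c in combos}
    for rep_seed in rep_ss.spawn(n_reps):
        streams = np.random.default_rng(rep_seed).spawn(2 + len(combos))
        cohort = simulate.simulate_cohort(params, streams[0])
        masked, _ = missingness.impose_missingness(cohort, intercepts,
                                                   config, streams[1])
        for combo, stream in zip(combos, streams[2:]):
            meth, rest = combo
            records[combo].append(run_method(meth, masked, rest, m, stream))

    rows = []
    truth = params.true_betas
    for (meth, rest), outcomes in records.items():
        ok = [o for o in outcomes if o.converged]
        for par in PARAMETERS:
            row = {"mechanism": mechanism, "proportion": proportion,
                   "method": meth, "restricted": rest, "parameter": par,
                   "truth": truth[par]}
            if len(ok) >= 2:
                row.update(compute_metrics(
                    [o.estimates[par] for o in ok],
                    [o.ses[par] for o in ok],
                    [o.cis[par] for o in ok],
                    truth[par], n_attempted=len(outcomes)))
                row["mean_violations"] = float(
                    np.mean([o.n_violations for o in ok]))
            else:
                row["nonconvergence_pct"] = 100.0
            rows.append(row)
    return pd.DataFrame(rows)


def run_study(grid: ScenarioGrid, params: SimulationParams) -> pd.DataFrame:
    """Run every cell of the grid and concatenate the performance tables."""
    tables = []
    for idx, (mech, prop) in enumerate(grid.cells()):
        tables.append(run_scenario(
            mech, prop, grid.methods, params, grid.n_reps, grid.m,
            seed=int(np.random.SeedSequence(
                entropy=grid.base_seed, spawn_key=(idx,)).generate_state(1)[0]
                % (2 ** 31)),
            restricted=grid.restriction_status))
    return pd.concat(tables, ignore_index=True)
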