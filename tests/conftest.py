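import numpy as np
import pytest

from restrictmi import SimulationParams, simulate_cohort
from restrictmi import missingness as ms
from restrictmi import restriction as rs


@pytest.fixture(scope="session")
def params():
    return SimulationParams(n_subjects=1000)


@pytest.fixture(scope="session")
def cohort(params):
    return simulate_cohort(params, np.random.default_rng(101))


@pytest.fixture(scope="session")
def weak65(params):
    """Calibrated weak-MAR / 65% scenario with one masked cohort."""
    config = ms.MissingnessConfig(mechanism="MAR_weak", overall_target=0.65)
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(202).spawn(7)]
    calib = [simulate_cohort(params, r) for r in rngs[:5]]
    intercepts = ms.calibrate_intercepts(calib, config)
    cohort = simulate_cohort(params, rngs[5])
    masked, mask = ms.impose_missingness(cohort, intercepts, config, rngs[6])
    assignment = rs.assignment_for_cohort(masked)
    return {"config": config, "intercepts": intercepts, "cohort": cohort,
            "masked": masked, "mask": mask, "assignment": assignment}
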