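"""Parameter containers for the simulation study.

The generative model mimics a prospective child cohort: a three-category
maternal-smoking exposure (0 = never-, 1 = ex-, 2 = current-smoker) measured
at waves 0..6 with forward-only transitions (an ever-smoker can never return
to "never"), a binary time-dependent auxiliary variable (maternal
depression), and a continuous outcome (BMI-for-age z-score, waves 2..6)
generated from a random-intercept linear model with the previous wave's
smoking category as the exposure.

Coefficient defaults are plausible stand-ins for a cohort of this kind
(smoking-in-pregnancy prevalence around 17%, a small ex-smoker category,
education and socio-economic status protective); every value can be
overridden, and the two exposure effects ``beta_smoking_ex`` (0.10) and
``beta_smoking_cur`` (0.15) are the estimands the evaluation harness reads
as truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

NEVER, EX, CURRENT = 0, 1, 2
SMOKING_WAVES = tuple(range(7))        # waves 0..6
MISSING_WAVES = tuple(range(1, 6))     # waves eligible for missingness
BMIZ_WAVES = tuple(range(2, 7))        # outcome waves
DEPRESSION_WAVES = tuple(range(6))     # waves 0..5


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its domain constraints."""


@dataclass
class CovariateParams:
    """Distributions of the time-independent covariates and depression model.

    Depression follows a first-order autoregressive logistic model: wave 0
    depends on ses and maternal age; later waves add a persistence term on
    the previous wave's status.
    """

    m_age_mean: float = 31.0          # years
    m_age_sd: float = 5.0
    m_education_prev: float = 0.60    # P(completed)
    breastfed_prev: float = 0.85
    sex_prev: float = 0.51            # P(male)
    birthweight_mean: float = 3.40    # kg
    birthweight_sd: float = 0.55
    ses_mean: float = 0.0             # z-score
    ses_sd: float = 1.0
    # child age at each wave (months); waves roughly biennial after infancy
    scage_means: tuple[float, ...] = (9.0, 33.0, 57.0, 81.0, 105.0, 129.0)
    scage_sd: float = 1.0
    # depression: logit P(dep_j=1) = icpt + b_ses*ses + b_age*(m_age-30)
    #             + b_prev*[dep_{j-1}=1]   (b_prev only for j>=1)
    dep_intercept0: float = -1.75
    dep_intercept: float = -2.20
    dep_b_ses: float = -0.30
    dep_b_age: float = -0.02
    dep_b_prev: float = 2.00

    def validate(self) -> None:
        for name in ("m_education_prev", "breastfed_prev", "sex_prev"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"{name}={p} must lie in (0,1)")
        for name in ("m_age_sd", "birthweight_sd", "ses_sd", "scage_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if len(self.scage_means) != 6:
            raise ConfigurationError("scage_means must list 6 wave ages")


@dataclass
class SimulationParams:
    """Full generative specification for one complete cohort.

    ``smoking_wave0_coefs`` parameterize a multinomial logistic model for
    smoking during pregnancy; ``never_transition_coefs`` the three-category
    multinomial for subjects who were never-smokers at the previous wave;
    ``ever_transition_coefs`` the binary (current vs ex) model for previous
    ever-smokers, whose structure enforces the forward-only restriction by
    construction.
    """

    n_subjects: int = 1000
    # wave-0 multinomial: rows (ex, current) x cols (icpt, m_age, m_educ, ses)
    smoking_wave0_coefs: tuple[tuple[float, float, float, float], ...] = (
        (-1.60, -0.02, -0.40, -0.20),   # ex-smoker
        (-0.20, -0.03, -0.70, -0.35),   # current-smoker
    )
    # never->{ex,current}: cols (icpt, m_age, m_educ, dep_prev, ses)
    never_transition_coefs: tuple[tuple[float, float, float, float, float], ...] = (
        (-4.20, -0.01, -0.30, 0.50, -0.20),
        (-3.20, -0.02, -0.40, 0.60, -0.30),
    )
    # ever -> current: (icpt, m_age, m_educ, dep_prev, prev_current, ses)
    ever_transition_coefs: tuple[float, float, float, float, float, float] = (
        -1.70, -0.005, -0.25, 0.40, 3.50, -0.20
    )
    # outcome model, fixed effects
    beta_intercept: float = 0.30
    beta_smoking_ex: float = 0.10     # estimand: ex vs never
    beta_smoking_cur: float = 0.15    # estimand: current vs never
    beta_scage: float = 0.002         # per month
    beta_breastfed: float = -0.10
    beta_m_age: float = -0.005
    beta_m_education: float = -0.10
    beta_birthweight: float = 0.20
    beta_sex: float = 0.05
    beta_ses: float = -0.05
    random_intercept_sd: float = 0.80  # BMIz units
    residual_sd: float = 0.60          # BMIz units
    covariates: CovariateParams = field(default_factory=CovariateParams)
    seed: int = 0

    @property
    def true_betas(self) -> dict[str, float]:
        """Truth for the two exposure coefficients, read by the evaluator."""
        return {"smoking_ex": self.beta_smoking_ex,
                "smoking_cur": self.beta_smoking_cur}

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.random_intercept_sd < 0:
            raise ConfigurationError("random_intercept_sd must be >= 0")
        if self.residual_sd <= 0:
            raise ConfigurationError("residual_sd must be > 0")
        if len(self.smoking_wave0_coefs) != 2 or any(
            len(row) != 4 for row in self.smoking_wave0_coefs
        ):
            raise ConfigurationError("smoking_wave0_coefs must be 2x4")
        if len(self.never_transition_coefs) != 2 or any(
            len(row) != 5 for row in self.never_transition_coefs
        ):
            raise ConfigurationError("never_transition_coefs must be 2x5")
        if len(self.ever_transition_coefs) != 6:
            raise ConfigurationError("ever_transition_coefs must have 6 entries")
        self.covariates.validate()

    # --- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationParams":
        raw = dict(raw)
        cov = raw.pop("covariates", None)
        params = cls(**{k: _tuplify(v) for k, v in raw.items()})
        if cov is not None:
            params.covariates = CovariateParams(
                **{k: _tuplify(v) for k, v in cov.items()}
            )
        params.validate()
        return params


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent generators from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


TIME_INDEPENDENT = ("m_age", "m_education", "breastfed", "ses", "sex",
                    "birthweight")

SMOKING_COLS = tuple(f"m_smoking{j}" for j in SMOKING_WAVES)
DEPRESSION_COLS = tuple(f"m_depression{j}" for j in DEPRESSION_WAVES)
BMIZ_COLS = tuple(f"BMIz{j}" for j in BMIZ_WAVES)
SCAGE_COLS = tuple(f"scage{j}" for j in range(1, 7))
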