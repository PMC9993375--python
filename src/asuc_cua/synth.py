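"""Synthetic trial-like patient data with the structure the analysis assumes.

Real patient-level data from the underlying pragmatic trial are access
restricted, so the pipeline ships a generator that emulates its printed
cohort statistics: two arms (infliximab, ciclosporin) of adults (18+)
hospitalised with steroid-resistant acute severe ulcerative colitis,
followed for two years for the colectomy endpoint, with event times drawn
from a proportional-hazards Weibull model

    S(t | x) = exp(-lambda * t**gamma * exp(x' beta))

and administrative censoring at the end of follow-up.  Covariates
(age-at-randomisation, weight) enter the linear predictor centred at the
arm means, so ``lambda`` is the baseline scale at the mean covariate
profile.

Payoff tables (state utilities and annual costs) are likewise synthetic
stand-ins for the unavailable trial appendix values; they are generated
deterministically from stated means, or stochastically (Beta utilities,
Gamma costs) for probabilistic sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import states
from .distributions import beta_from_moments, gamma_from_moments
from .errors import ValidationError

ARMS = ("infliximab", "ciclosporin")

#: physiological floors for truncated covariate draws
MIN_AGE_YEARS = 18.0
MIN_WEIGHT_KG = 30.0

#: CSV column layout for patient tables
PATIENT_COLUMNS = ("arm", "age_at_randomisation", "weight", "observed_time_years", "event")


@dataclass(frozen=True)
class WeibullEventModel:
    """Generating proportional-hazards Weibull parameters for one arm."""

    shape: float  # gamma; <1 means a declining colectomy hazard
    scale: float  # lambda, per year**gamma, at the mean covariate profile
    beta_age: float = 0.0  # log hazard ratio per year of age
    beta_weight: float = 0.0  # log hazard ratio per kg

    def validate(self, prefix: str = "event_model") -> list[str]:
        problems = []
        if not self.shape > 0:
            problems.append(f"{prefix}.shape must be > 0; got {self.shape}")
        if not self.scale > 0:
            problems.append(f"{prefix}.scale must be > 0; got {self.scale}")
        return problems


@dataclass(frozen=True)
class ArmSpec:
    """Cohort description for one treatment arm."""

    n: int
    age_mean: float
    age_sd: float
    weight_mean: float
    weight_sd: float
    event_model: WeibullEventModel

    def validate(self, prefix: str) -> list[str]:
        problems = []
        if self.n < 0:
            problems.append(f"{prefix}.n must be >= 0; got {self.n}")
        if self.age_sd < 0:
            problems.append(f"{prefix}.age_sd must be >= 0; got {self.age_sd}")
        if self.weight_sd < 0:
            problems.append(f"{prefix}.weight_sd must be >= 0; got {self.weight_sd}")
        problems += self.event_model.validate(f"{prefix}.event_model")
        return problems


@dataclass(frozen=True)
class CohortSpec:
    """Full two-arm synthetic cohort specification."""

    arms: Mapping[str, ArmSpec]
    censor_time: float = 2.0  # years of administrative follow-up
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if self.censor_time <= 0:
            problems.append(f"censor_time must be > 0; got {self.censor_time}")
        for arm, spec in self.arms.items():
            problems += spec.validate(f"arms[{arm}]")
        return problems


def sample_event_times(
    shape: float,
    scale: float,
    linear_predictor: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw latent event times from the proportional-hazards Weibull model.

    Inverts S(t) = exp(-scale * t**shape * exp(lp)):
    T = (-ln U / (scale * exp(lp)))**(1/shape) with U ~ Uniform(0, 1).
    """
    if not shape > 0:
        raise ValidationError(f"shape must be > 0; got {shape}")
    if not scale > 0:
        raise ValidationError(f"scale must be > 0; got {scale}")
    lp = np.asarray(linear_predictor, dtype=float)
    u = rng.uniform(size=lp.shape)
    return (-np.log(u) / (scale * np.exp(lp))) ** (1.0 / shape)


def _truncated_normal(
    mean: float, sd: float, lower: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws from a normal truncated below at ``lower`` whose *truncated*
    mean equals ``mean`` (the printed cohort means describe the truncated
    population, so the location parameter is calibrated accordingly)."""
    if sd == 0.0:
        if mean < lower:
            raise ValidationError(f"degenerate draw {mean} below floor {lower}")
        return np.full(size, mean)
    if mean <= lower:
        raise ValidationError(f"mean {mean} must exceed the truncation floor {lower}")

    def trunc_mean_gap(loc):
        return stats.truncnorm.mean((lower - loc) / sd, np.inf, loc=loc, scale=sd) - mean

    from scipy.optimize import brentq

    lo = lower - 10.0 * sd
    loc = brentq(trunc_mean_gap, lo, mean) if trunc_mean_gap(mean) > 1e-12 else mean
    a = (lower - loc) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate a two-arm patient table; deterministic given ``spec.seed``.

    Returns a DataFrame with columns ``arm``, ``age_at_randomisation``,
    ``weight``, ``observed_time_years`` and ``event`` (1 = colectomy
    observed, 0 = administratively censored at ``censor_time``).
    """
    problems = spec.validate()
    if problems:
        raise ValidationError(problems)
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    frames = []
    for arm, arm_spec in spec.arms.items():
        n = arm_spec.n
        if n == 0:
            continue
        age = _truncated_normal(arm_spec.age_mean, arm_spec.age_sd, MIN_AGE_YEARS, n, rng)
        weight = _truncated_normal(
            arm_spec.weight_mean, arm_spec.weight_sd, MIN_WEIGHT_KG, n, rng
        )
        em = arm_spec.event_model
        # linear predictor centred at the arm means: lambda is the scale at
        # the mean covariate profile
        lp = em.beta_age * (age - arm_spec.age_mean) + em.beta_weight * (
            weight - arm_spec.weight_mean
        )
        latent = sample_event_times(em.shape, em.scale, lp, rng)
        event = latent <= spec.censor_time
        observed = np.where(event, latent, spec.censor_time)
        frames.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "age_at_randomisation": age,
                    "weight": weight,
                    "observed_time_years": observed,
                    "event": event.astype(int),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PATIENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[list(PATIENT_COLUMNS)]


def write_patients_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_patients_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class PayoffTable:
    """Per-state annual payoffs plus one-off event payoffs for one arm.

    ``utilities`` are QALY weights per year (EQ-5D-3L UK tariff range
    [-0.594, 1]); ``annual_costs`` are GBP per year in a state;
    ``one_off_costs`` are GBP charged once on entry into an event
    (``surgery``, ``complication``); ``one_off_utility_decrements`` are
    one-time QALY losses on the same events.
    """

    utilities: dict[str, float]
    annual_costs: dict[str, float]
    one_off_costs: dict[str, float] = field(default_factory=dict)
    one_off_utility_decrements: dict[str, float] = field(default_factory=dict)

    def validate(self, prefix: str = "payoffs") -> list[str]:
        problems = []
        for state, u in self.utilities.items():
            if not states.UTILITY_MIN <= u <= states.UTILITY_MAX:
                problems.append(
                    f"{prefix}.utilities[{state}]={u} outside "
                    f"[{states.UTILITY_MIN}, {states.UTILITY_MAX}]"
                )
        for state, c in self.annual_costs.items():
            if c < 0:
                problems.append(f"{prefix}.annual_costs[{state}]={c} must be >= 0")
        for ev, c in self.one_off_costs.items():
            if c < 0:
                problems.append(f"{prefix}.one_off_costs[{ev}]={c} must be >= 0")
        return problems

    def scaled_utilities(self, factor: float) -> "PayoffTable":
        """Return a copy with every state utility multiplied by ``factor``."""
        return replace(
            self, utilities={s: u * factor for s, u in self.utilities.items()}
        )


def make_payoff_table(
    state_means: PayoffTable,
    state_ses: PayoffTable | None = None,
    rng: np.random.Generator | None = None,
) -> PayoffTable:
    """Build a payoff table from stated means, optionally as a stochastic draw.

    With ``rng`` absent the means are stored exactly.  With ``rng`` given,
    utilities are drawn from moment-matched Beta distributions and costs
    from moment-matched Gamma distributions (an SE of zero keeps the mean
    exactly); this is the per-draw sampler used by the PSA.  The dead-state
    utility is pinned at its mean (zero by convention), never drawn.
    """
    problems = state_means.validate("state_means")
    if problems:
        raise ValidationError(problems)
    if rng is None or state_ses is None:
        return replace(
            state_means,
            utilities=dict(state_means.utilities),
            annual_costs=dict(state_means.annual_costs),
            one_off_costs=dict(state_means.one_off_costs),
            one_off_utility_decrements=dict(state_means.one_off_utility_decrements),
        )

    def draw_utility(mean, se):
        if se == 0.0 or mean <= 0.0 or mean >= 1.0:
            return mean
        a, b = beta_from_moments(mean, se)
        return float(rng.beta(a, b))

    def draw_cost(mean, se):
        if se == 0.0 or mean <= 0.0:
            return mean
        shape, scale = gamma_from_moments(mean, se)
        return float(rng.gamma(shape, scale))

    return PayoffTable(
        utilities={
            s: (0.0 if s == states.DEAD else draw_utility(u, state_ses.utilities.get(s, 0.0)))
            for s, u in state_means.utilities.items()
        },
        annual_costs={
            s: draw_cost(c, state_ses.annual_costs.get(s, 0.0))
            for s, c in state_means.annual_costs.items()
        },
        one_off_costs={
            ev: draw_cost(c, state_ses.one_off_costs.get(ev, 0.0))
            for ev, c in state_means.one_off_costs.items()
        },
        one_off_utility_decrements=dict(state_means.one_off_utility_decrements),
    )
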