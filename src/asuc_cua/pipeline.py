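"""End-to-end model pipeline: resolved inputs and per-arm evaluation.

``ModelInputs`` is the fully resolved, deterministic parameter set for both
arms (decision-tree probabilities, Weibull extrapolation parameters, annual
mortality, payoffs with the drug component kept separate).  ``run_arm``
evaluates one arm through the decision tree and the Markov cohort model and
returns the combined discounted totals; the scenario engine and the PSA
re-run it with targeted modifications.

The cohort entering the Markov stage is the end-of-tree state distribution
(survivors in medical or surgical remission; perioperative deaths carried
forward as dead mass), so cohort mass is conserved across the seam and
discounting continues with year offset 2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from . import states
from .cea import ArmResult, CEComparison, combine_dt_mm, incremental
from .config import RunConfig
from .decision_tree import ArmDTParams, DTResult, build_tree, evaluate_tree
from .errors import ValidationError
from .markov import MMResult, TransitionModel, accumulate_payoffs, run_cohort
from .survival import annualise_probability, fixed_tp_schedule, weibull_tp_schedule
from .synth import PayoffTable

REFERENCE_ARM = "infliximab"
COMPARATOR_ARM = "ciclosporin"


@dataclass(frozen=True)
class ArmInputs:
    """Resolved deterministic inputs for one arm."""

    dt: "ArmDTConfigLike"
    base_payoffs: PayoffTable  # state payoffs excluding the drug component
    annual_drug_cost: float  # GBP/year added to remission-state cost
    weibull_shape: float
    weibull_scale: float
    fixed_tp: float


@dataclass(frozen=True)
class ArmDTConfigLike:
    p_initial_remission: float
    p_colectomy_mid: float
    p_colectomy_late: float
    p_postop_complication: float
    p_death_surgery: float
    drug_cost_initial: float


@dataclass(frozen=True)
class ModelInputs:
    """Everything needed to evaluate both arms deterministically."""

    arms: Mapping[str, ArmInputs]
    p_complication_given_surgery: float
    p_complication_resolution: float
    mortality_no_colectomy_annual: float
    mortality_emergency_annual: float
    discount_rate: float
    wtp: float
    horizon_years: int
    half_cycle_correction: bool = False


def build_inputs(
    config: RunConfig, weibull_params: Mapping[str, tuple[float, float]]
) -> ModelInputs:
    """Resolve a validated config plus fitted Weibull (shape, scale) per arm.

    ``weibull_params`` typically comes from fitting the synthetic cohort;
    the generating values from the config can be passed to skip fitting.
    Published multi-year mortality probabilities are converted to annual via
    the constant-rate transform here.
    """
    arms = {}
    for arm, dt_cfg in config.decision_tree.items():
        pay_cfg = config.payoffs[arm]
        shape, scale = weibull_params[arm]
        arms[arm] = ArmInputs(
            dt=ArmDTConfigLike(
                p_initial_remission=dt_cfg.p_initial_remission,
                p_colectomy_mid=dt_cfg.p_colectomy_mid,
                p_colectomy_late=dt_cfg.p_colectomy_late,
                p_postop_complication=dt_cfg.p_postop_complication,
                p_death_surgery=dt_cfg.p_death_surgery,
                drug_cost_initial=dt_cfg.drug_cost_initial,
            ),
            base_payoffs=pay_cfg.payoffs,
            annual_drug_cost=pay_cfg.annual_drug_cost_remission,
            weibull_shape=shape,
            weibull_scale=scale,
            fixed_tp=config.markov.fixed_tp.get(arm, 0.0),
        )
    mort = config.markov.mortality
    return ModelInputs(
        arms=arms,
        p_complication_given_surgery=config.markov.p_complication_given_surgery,
        p_complication_resolution=config.markov.p_complication_resolution,
        mortality_no_colectomy_annual=annualise_probability(
            mort.no_colectomy, mort.period_years
        ),
        mortality_emergency_annual=annualise_probability(
            mort.emergency_colectomy, mort.period_years
        ),
        discount_rate=config.economics.discount_rate,
        wtp=config.economics.wtp,
        horizon_years=config.economics.horizon_years,
        half_cycle_correction=config.markov.half_cycle_correction,
    )


def end_of_tree_distribution(dt_result_paths, tree) -> np.ndarray:
    """Markov initial distribution: terminal state of each tree pathway."""
    x0 = np.zeros(len(states.STATES))
    for path in tree.paths:
        final_state = path.segments[-1][0]
        x0[states.STATE_INDEX[final_state]] += path.probability
    return x0


@dataclass
class ArmEvaluation:
    arm: str
    combined: ArmResult
    dt: DTResult
    mm: MMResult


def run_arm(
    inputs: ModelInputs,
    arm: str,
    *,
    horizon_years: int | None = None,
    price_multiplier: float = 1.0,
    utility_multiplier: float = 1.0,
    tp_mode: str = "weibull_time_dependent",
    weibull: tuple[float, float] | None = None,
    base_payoffs: PayoffTable | None = None,
    mortality: tuple[float, float] | None = None,
) -> ArmEvaluation:
    """Evaluate one arm through DT + MM under optional modifications.

    ``price_multiplier`` rescales both drug components (induction cost and
    ongoing annual drug cost); ``utility_multiplier`` rescales every state
    utility; ``weibull``/``base_payoffs``/``mortality`` override the
    resolved inputs (used by the PSA draws); ``tp_mode='fixed'`` swaps the
    Weibull schedule for the arm's fixed annual colectomy probability.
    """
    if arm not in inputs.arms:
        raise ValidationError(f"unknown arm {arm!r}")
    ai = inputs.arms[arm]
    horizon = inputs.horizon_years if horizon_years is None else horizon_years
    mm_cycles = int(horizon) - 2
    if mm_cycles < 1:
        raise ValidationError(f"horizon_years={horizon} leaves no Markov cycles")

    pay = base_payoffs if base_payoffs is not None else ai.base_payoffs
    if utility_multiplier != 1.0:
        pay = pay.scaled_utilities(utility_multiplier)
    # fold the (possibly rescaled) ongoing drug cost into the remission state
    costs = dict(pay.annual_costs)
    costs[states.REMISSION_MED] = (
        costs.get(states.REMISSION_MED, 0.0) + ai.annual_drug_cost * price_multiplier
    )
    pay = replace(pay, annual_costs=costs)

    dt_params = ArmDTParams(
        p_initial_remission=ai.dt.p_initial_remission,
        p_colectomy_mid=ai.dt.p_colectomy_mid,
        p_colectomy_late=ai.dt.p_colectomy_late,
        p_postop_complication=ai.dt.p_postop_complication,
        p_death_surgery=ai.dt.p_death_surgery,
        drug_cost_initial=ai.dt.drug_cost_initial * price_multiplier,
        payoffs=pay,
    )
    tree = build_tree(arm, dt_params)
    dt_result = evaluate_tree(tree, discount_rate=inputs.discount_rate)

    if tp_mode == "fixed":
        schedule = fixed_tp_schedule(ai.fixed_tp, mm_cycles)
    elif tp_mode == "weibull_time_dependent":
        shape, scale = weibull if weibull is not None else (ai.weibull_shape, ai.weibull_scale)
        # the extrapolation clock restarts at Markov entry: cycle t of the
        # long-term model uses the Weibull tp for model year t
        schedule = weibull_tp_schedule(shape, scale, mm_cycles)
    else:
        raise ValidationError(f"unknown tp_mode {tp_mode!r}")

    m0, me = mortality if mortality is not None else (
        inputs.mortality_no_colectomy_annual, inputs.mortality_emergency_annual
    )
    model = TransitionModel(
        tp_colectomy=schedule,
        p_complication_given_surgery=inputs.p_complication_given_surgery,
        annual_mortality_no_colectomy=m0,
        annual_mortality_emergency_colectomy=me,
        p_complication_resolution=inputs.p_complication_resolution,
    )
    x0 = end_of_tree_distribution(dt_result, tree)
    trace = run_cohort(x0, model, mm_cycles)
    mm_result = accumulate_payoffs(
        trace,
        pay,
        discount_rate=inputs.discount_rate,
        year_offset=2,
        half_cycle_correction=inputs.half_cycle_correction,
        arm=arm,
    )
    combined = combine_dt_mm(dt_result, mm_result, horizon_years=float(horizon))
    return ArmEvaluation(arm=arm, combined=combined, dt=dt_result, mm=mm_result)


@dataclass
class BaseCaseResult:
    reference: ArmEvaluation
    comparator: ArmEvaluation
    comparison: CEComparison


def run_base_case(inputs: ModelInputs, **overrides) -> BaseCaseResult:
    """Evaluate both arms and the incremental comparison (comparator =
    ciclosporin vs reference = infliximab)."""
    per_arm = overrides.pop("per_arm", None) or {}
    ref_over = dict(overrides)
    comp_over = dict(overrides)
    # the shared price multiplier targets the infliximab biosimilar price only
    comp_over.pop("price_multiplier", None)
    ref_over.update(per_arm.get(REFERENCE_ARM, {}))
    comp_over.update(per_arm.get(COMPARATOR_ARM, {}))
    ref = run_arm(inputs, REFERENCE_ARM, **ref_over)
    comp = run_arm(inputs, COMPARATOR_ARM, **comp_over)
    comparison = incremental(ref.combined, comp.combined, wtp=inputs.wtp)
    return BaseCaseResult(reference=ref, comparator=comp, comparison=comparison)
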