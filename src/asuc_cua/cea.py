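"""Incremental cost-effectiveness calculus for two-strategy comparisons.

Combines the two-year decision-tree and 18-year Markov components into
per-arm totals, computes incremental cost and QALYs (comparator minus
reference), classifies the result on the cost-effectiveness plane
(dominance or an ICER in the NE/SW quadrants), and evaluates net monetary
and net health benefit at a willingness-to-pay threshold (default
GBP 20,000 per QALY, the NICE convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .decision_tree import DTResult
from .errors import ValidationError
from .markov import MMResult

DEFAULT_WTP = 20_000.0
DEFAULT_DISCOUNT_RATE = 0.035


def discount_factor(year_index: int, rate: float = DEFAULT_DISCOUNT_RATE) -> float:
    """Annual discount factor: 1 for year 1, (1+r)**-(y-1) thereafter.

    The first 12 months of the model are undiscounted; each later calendar
    year y carries (1+r)**-(y-1).
    """
    if year_index < 1:
        raise ValidationError(f"year_index must be >= 1; got {year_index}")
    if rate < 0:
        raise ValidationError(f"rate must be >= 0; got {rate}")
    return (1.0 + rate) ** -(year_index - 1)


@dataclass(frozen=True)
class ArmResult:
    """Total discounted cost and QALYs for one strategy over the horizon."""

    arm: str
    cost: float
    qaly: float
    horizon_years: float

    def __post_init__(self):
        if not (math.isfinite(self.cost) and math.isfinite(self.qaly)):
            raise ValidationError(f"non-finite arm result for {self.arm}")


def combine_dt_mm(dt: DTResult, mm: MMResult, horizon_years: float) -> ArmResult:
    """Sum decision-tree and Markov components into the combined arm total.

    Valid because the Markov stage is discounted with a year offset that
    places its first cycle immediately after the two tree years.
    """
    if dt.arm and mm.arm and dt.arm != mm.arm:
        raise ValidationError(f"arm mismatch: DT {dt.arm!r} vs MM {mm.arm!r}")
    return ArmResult(
        arm=dt.arm,
        cost=dt.expected_cost + mm.discounted_cost,
        qaly=dt.expected_qaly + mm.discounted_qaly,
        horizon_years=horizon_years,
    )


@dataclass(frozen=True)
class CEComparison:
    """Incremental comparison of comparator vs reference."""

    reference: str
    comparator: str
    delta_cost: float  # comparator - reference, GBP
    delta_qaly: float
    icer: float | None  # GBP/QALY; None when dominance applies or dQALY=0
    classification: str
    wtp: float
    nmb: float  # net monetary benefit of comparator at wtp, GBP
    nhb: float  # net health benefit, QALYs


def incremental(
    reference: ArmResult, comparator: ArmResult, wtp: float = DEFAULT_WTP
) -> CEComparison:
    """Classify the comparator against the reference on the CE plane.

    The comparator dominates iff it is cheaper and more effective
    (delta_cost < 0, delta_qaly > 0); the reference dominates in the mirror
    case.  An ICER is reported only in the NE (more costly, more effective)
    and SW (cheaper, less effective) quadrants.  Zero-delta edges are
    classified by the sign of the remaining delta, with no ICER.
    """
    if reference.horizon_years != comparator.horizon_years:
        raise ValidationError(
            f"horizon mismatch: {reference.horizon_years} vs {comparator.horizon_years}"
        )
    if wtp <= 0:
        raise ValidationError(f"wtp must be > 0; got {wtp}")
    dc = comparator.cost - reference.cost
    de = comparator.qaly - reference.qaly
    icer = None
    if dc < 0 and de > 0:
        cls = f"{comparator.arm} dominates"
    elif dc > 0 and de < 0:
        cls = f"{reference.arm} dominates"
    elif de == 0:
        if dc == 0:
            cls = "equivalent"
        elif dc < 0:
            cls = f"{comparator.arm} dominates"  # cheaper, equal effect (weak)
        else:
            cls = f"{reference.arm} dominates"
    elif dc == 0:
        cls = f"{comparator.arm} dominates" if de > 0 else f"{reference.arm} dominates"
    else:
        icer = dc / de
        cls = "ICER (NE quadrant)" if dc > 0 else "ICER (SW quadrant)"
    return CEComparison(
        reference=reference.arm,
        comparator=comparator.arm,
        delta_cost=dc,
        delta_qaly=de,
        icer=icer,
        classification=cls,
        wtp=wtp,
        nmb=wtp * de - dc,
        nhb=de - dc / wtp,
    )


def results_table(
    reference: ArmResult, comparator: ArmResult, comparison: CEComparison, label: str = "base_case"
) -> pd.DataFrame:
    """One-row summary table mirroring the usual base-case result layout."""
    return pd.DataFrame(
        [
            {
                "scenario": label,
                f"cost_{reference.arm}": reference.cost,
                f"qaly_{reference.arm}": reference.qaly,
                f"cost_{comparator.arm}": comparator.cost,
                f"qaly_{comparator.arm}": comparator.qaly,
                "delta_cost": comparison.delta_cost,
                "delta_qaly": comparison.delta_qaly,
                "icer": comparison.icer,
                "cost_effectiveness": comparison.classification,
                "nmb": comparison.nmb,
                "nhb": comparison.nhb,
            }
        ]
    )


def predict_price_scenario_cost(
    base_cost: float, cost_at_small_reduction: float, small_reduction: float, reduction: float
) -> float:
    """Linear extrapolation of an arm cost under a drug price reduction.

    Arm cost is exactly linear in the unit drug price, so the discounted
    drug-cost component D = (base - cost_at_small_reduction)/small_reduction
    and cost at any reduction f is base - f*D.
    """
    if not 0 < small_reduction < 1:
        raise ValidationError("small_reduction must lie in (0, 1)")
    drug_component = (base_cost - cost_at_small_reduction) / small_reduction
    return base_cost - reduction * drug_component
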