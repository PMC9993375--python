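"""Two-year decision tree for the acute phase of rescue therapy.

Both arms share one topology over three periods — 0-3 months, 4-12 months,
13-24 months.  After induction therapy a patient either achieves remission
or fails and undergoes colectomy.  Remitters can lose response and undergo
colectomy mid-period (8 months in period 2, 18.5 months in period 3).
Every colectomy resolves to one of: straight post-surgical remission, a
post-operative complication (treated, with surgical remission achieved at
the start of the next period), or perioperative death.  Dead paths accrue
nothing further.

Payoffs accrue piecewise over the path's state segments (utility x duration
for QALYs, annual cost x duration plus one-off surgery/complication/drug
costs).  Accruals beyond 12 months are discounted by one annual factor
1/(1+r), matching the yearly-compounding convention of the companion
cohort model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import pandas as pd

from . import states
from .errors import ValidationError
from .synth import PayoffTable

HORIZON_YEARS = 2.0
#: period boundaries in years: 0-3 m, 4-12 m, 13-24 m
PERIOD_ENDS = (0.25, 1.0, 2.0)
#: assumed timing of colectomy within each period (mid-period)
COLECTOMY_TIME = {1: 0.125, 2: 8.0 / 12.0, 3: 18.5 / 12.0}

#: fixed pathway count of the shared topology: three colectomy entry points
#: x three surgical resolutions, plus sustained remission
N_PATHS = 10


@dataclass(frozen=True)
class ArmDTParams:
    """Decision-tree inputs for one arm."""

    p_initial_remission: float  # remission (vs immediate treatment failure) in period 1
    p_colectomy_mid: float  # colectomy in period 2, given remission entering it
    p_colectomy_late: float  # colectomy in period 3, given remission entering it
    p_postop_complication: float
    p_death_surgery: float
    drug_cost_initial: float  # GBP, induction drug acquisition, charged at t=0
    payoffs: PayoffTable

    def validate(self, prefix: str = "decision_tree") -> list[str]:
        problems = []
        for name in (
            "p_initial_remission",
            "p_colectomy_mid",
            "p_colectomy_late",
            "p_postop_complication",
            "p_death_surgery",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{prefix}.{name}={v} outside [0, 1]")
        if self.p_postop_complication + self.p_death_surgery > 1.0 + 1e-12:
            problems.append(
                f"{prefix}: p_postop_complication + p_death_surgery = "
                f"{self.p_postop_complication + self.p_death_surgery} exceeds 1"
            )
        if self.drug_cost_initial < 0:
            problems.append(f"{prefix}.drug_cost_initial must be >= 0")
        problems += self.payoffs.validate(f"{prefix}.payoffs")
        return problems


@dataclass(frozen=True)
class PathSpec:
    """One root-to-leaf pathway: branch probability, state segments, events."""

    label: str
    probability: float
    #: (state, start_year, end_year) occupancy segments; DEAD segments accrue nothing
    segments: tuple[tuple[str, float, float], ...]
    #: (event_name, time_year) one-off payoffs: "drug", "surgery", "complication"
    events: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class DecisionTree:
    """Evaluated-ready tree for one arm (fixed shared topology)."""

    arm: str
    params: ArmDTParams
    paths: tuple[PathSpec, ...]


@dataclass
class DTResult:
    """Expected discounted payoffs over the two-year tree horizon."""

    arm: str
    expected_cost: float
    expected_qaly: float
    path_table: pd.DataFrame  # per-path probability, cost, qaly


def _surgery_resolutions(params: ArmDTParams, period: int, t_surg: float, p_reach: float,
                         prefix: str, pre_segments):
    """The three post-colectomy branches from a colectomy at ``t_surg``."""
    pc = params.p_postop_complication
    pd_ = params.p_death_surgery
    period_end = PERIOD_ENDS[period - 1]
    out = []
    # straight surgical remission for the rest of the horizon
    out.append(
        PathSpec(
            label=f"{prefix}:surgical_remission",
            probability=p_reach * (1.0 - pc - pd_),
            segments=tuple(pre_segments)
            + ((states.SURG_REMISSION, t_surg, HORIZON_YEARS),),
            events=(("drug", 0.0), ("surgery", t_surg)),
        )
    )
    # complication treated within the period, surgical remission from next period
    comp_end = min(period_end, HORIZON_YEARS)
    comp_segments = tuple(pre_segments) + ((states.COMPLICATIONS, t_surg, comp_end),)
    if comp_end < HORIZON_YEARS:
        comp_segments += ((states.SURG_REMISSION, comp_end, HORIZON_YEARS),)
    out.append(
        PathSpec(
            label=f"{prefix}:complication",
            probability=p_reach * pc,
            segments=comp_segments,
            events=(("drug", 0.0), ("surgery", t_surg), ("complication", t_surg)),
        )
    )
    # perioperative death: no further accrual
    out.append(
        PathSpec(
            label=f"{prefix}:death",
            probability=p_reach * pd_,
            segments=tuple(pre_segments) + ((states.DEAD, t_surg, HORIZON_YEARS),),
            events=(("drug", 0.0), ("surgery", t_surg)),
        )
    )
    return out


def build_tree(arm: str, params: ArmDTParams) -> DecisionTree:
    """Enumerate the shared 10-pathway topology with this arm's parameters."""
    problems = params.validate()
    if problems:
        raise ValidationError(problems)
    p1 = params.p_initial_remission
    p2 = params.p_colectomy_mid
    p3 = params.p_colectomy_late
    paths: list[PathSpec] = []

    # period-1 treatment failure -> immediate colectomy
    t1 = COLECTOMY_TIME[1]
    paths += _surgery_resolutions(
        params, 1, t1, 1.0 - p1, "fail_initial",
        [(states.REMISSION_MED, 0.0, t1)],
    )
    # period-2 loss of response
    t2 = COLECTOMY_TIME[2]
    paths += _surgery_resolutions(
        params, 2, t2, p1 * p2, "relapse_mid",
        [(states.REMISSION_MED, 0.0, t2)],
    )
    # period-3 loss of response
    t3 = COLECTOMY_TIME[3]
    paths += _surgery_resolutions(
        params, 3, t3, p1 * (1.0 - p2) * p3, "relapse_late",
        [(states.REMISSION_MED, 0.0, t3)],
    )
    # sustained remission on medical therapy
    paths.append(
        PathSpec(
            label="sustained_remission",
            probability=p1 * (1.0 - p2) * (1.0 - p3),
            segments=((states.REMISSION_MED, 0.0, HORIZON_YEARS),),
            events=(("drug", 0.0),),
        )
    )

    total = sum(p.probability for p in paths)
    if abs(total - 1.0) > 1e-12:
        raise ValidationError(f"path probabilities sum to {total!r}, not 1")
    return DecisionTree(arm=arm, params=params, paths=tuple(paths))


def path_probabilities(tree: DecisionTree) -> list[float]:
    """Branch-product probability of each root-to-leaf pathway (sums to 1)."""
    return [p.probability for p in tree.paths]


def _discounted_duration(a: float, b: float, rate: float) -> float:
    """Integral of 1 over [a, b] years with the second year discounted.

    Per the yearly convention, accrual within the first 12 months is
    undiscounted and accrual in months 13-24 carries one factor 1/(1+r).
    """
    if b <= a:
        return 0.0
    first = max(0.0, min(b, 1.0) - min(a, 1.0))
    second = max(0.0, b - max(a, 1.0))
    return first + second / (1.0 + rate)


def _event_factor(t: float, rate: float) -> float:
    return 1.0 if t <= 1.0 else 1.0 / (1.0 + rate)


def evaluate_tree(tree: DecisionTree, discount_rate: float = 0.035) -> DTResult:
    """Expected discounted cost and QALYs as probability-weighted path sums."""
    pay = tree.params.payoffs
    rows = []
    for path in tree.paths:
        qaly = 0.0
        cost = 0.0
        for state, a, b in path.segments:
            if state == states.DEAD:
                continue
            try:
                u = pay.utilities[state]
                c = pay.annual_costs[state]
            except KeyError as exc:
                raise ValidationError(
                    f"missing payoff for state {exc.args[0]!r} on path {path.label!r}"
                ) from exc
            dur = _discounted_duration(a, b, discount_rate)
            qaly += u * dur
            cost += c * dur
        for event, t in path.events:
            f = _event_factor(t, discount_rate)
            if event == "drug":
                cost += tree.params.drug_cost_initial * f
            else:
                cost += pay.one_off_costs.get(event, 0.0) * f
                qaly -= pay.one_off_utility_decrements.get(event, 0.0) * f
        rows.append(
            {"path": path.label, "probability": path.probability, "cost": cost, "qaly": qaly}
        )
    table = pd.DataFrame(rows)
    return DTResult(
        arm=tree.arm,
        expected_cost=float((table["probability"] * table["cost"]).sum()),
        expected_qaly=float((table["probability"] * table["qaly"]).sum()),
        path_table=table,
    )


def scale_drug_price(params: ArmDTParams, multiplier: float) -> ArmDTParams:
    """Rescale the induction drug-acquisition cost (price scenarios)."""
    if multiplier <= 0:
        raise ValidationError(f"price multiplier must be > 0; got {multiplier}")
    return replace(params, drug_cost_initial=params.drug_cost_initial * multiplier)
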