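"""Annual-cycle Markov cohort model for the long-term phase (18 years).

Patients leaving the two-year decision tree in remission enter a five-state
cohort model: remission on medical therapy, surgery (a transient
within-cycle colectomy event), post-surgical complications, surgical
remission, and death.  The colectomy transition out of remission follows a
per-cycle schedule (time-dependent Weibull-derived or fixed).  Surgery
resolves within its cycle — mortality from the emergency-colectomy rate
first, then complications among survivors — so cohort mass is attributed to
the destination state and surgery itself carries only one-off payoffs.
Complications resolve to surgical remission in the following cycle.
Background mortality at the 'no colectomy' rate applies in both remission
states.  Competing risks within a cycle are sequenced death-first, keeping
every row of the transition matrix in [0, 1] for any valid inputs.

Cycle payoffs are discounted at a fixed annual rate with a configurable
year offset, so that Markov cycle 1 is calendar year ``year_offset + 1`` of
the combined model and discounting is continuous across the decision-tree
seam (cycle t carries the factor (1+r)**-(t + year_offset - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import states
from .errors import ValidationError
from .states import COMPLICATIONS, DEAD, REMISSION_MED, STATE_INDEX, STATES, SURG_REMISSION, SURGERY
from .survival import TPSchedule
from .synth import PayoffTable

_N = len(STATES)
_ROW_TOL = 1e-12


@dataclass(frozen=True)
class TransitionModel:
    """All inputs needed to build the per-cycle transition matrices."""

    tp_colectomy: TPSchedule
    p_complication_given_surgery: float
    annual_mortality_no_colectomy: float  # remission states, per cycle
    annual_mortality_emergency_colectomy: float  # applied in the surgery cycle
    p_complication_resolution: float = 1.0  # recovery to surgical remission next cycle

    def validate(self, prefix: str = "markov") -> list[str]:
        problems = []
        for name in (
            "p_complication_given_surgery",
            "annual_mortality_no_colectomy",
            "annual_mortality_emergency_colectomy",
            "p_complication_resolution",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{prefix}.{name}={v} outside [0, 1]")
        return problems


@dataclass
class CohortTrace:
    """State-occupancy bookkeeping: rows are cycles 0..H, columns ``STATES``.

    ``surgery_inflow``/``complication_inflow`` record the cohort mass
    entering those transient events in each cycle (1..H), which is what the
    one-off payoffs apply to.
    """

    occupancy: np.ndarray
    surgery_inflow: np.ndarray = field(default_factory=lambda: np.zeros(0))
    complication_inflow: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class MMResult:
    """Discounted totals from the cohort model."""

    arm: str
    discounted_cost: float
    discounted_qaly: float
    trace: CohortTrace | None = None
    se_cost: float | None = None  # populated by microsimulation only
    se_qaly: float | None = None


def _surgery_row(model: TransitionModel) -> np.ndarray:
    """Within-cycle resolution of a colectomy: death first, then complications."""
    me = model.annual_mortality_emergency_colectomy
    pc = model.p_complication_given_surgery
    row = np.zeros(_N)
    row[STATE_INDEX[DEAD]] = me
    row[STATE_INDEX[COMPLICATIONS]] = (1.0 - me) * pc
    row[STATE_INDEX[SURG_REMISSION]] = (1.0 - me) * (1.0 - pc)
    return row


def build_cycle_matrix(cycle: int, model: TransitionModel) -> np.ndarray:
    """Stochastic matrix for model year ``cycle`` (1-based), order ``STATES``.

    The surgery tunnel is composed into the remission row, so no end-of-cycle
    mass ever sits in SURGERY.
    """
    problems = model.validate()
    if problems:
        raise ValidationError(problems)
    if not 1 <= cycle <= len(model.tp_colectomy):
        raise ValidationError(
            f"cycle {cycle} outside schedule of length {len(model.tp_colectomy)}"
        )
    q = model.tp_colectomy.tp(cycle)
    m0 = model.annual_mortality_no_colectomy
    pres = model.p_complication_resolution
    me = model.annual_mortality_emergency_colectomy

    M = np.zeros((_N, _N))
    surg = _surgery_row(model)

    i = STATE_INDEX[REMISSION_MED]
    M[i] = (1.0 - m0) * q * surg  # colectomy among cycle survivors
    M[i, STATE_INDEX[REMISSION_MED]] = (1.0 - m0) * (1.0 - q)
    M[i, STATE_INDEX[DEAD]] += m0

    M[STATE_INDEX[SURGERY]] = surg

    i = STATE_INDEX[COMPLICATIONS]
    M[i, STATE_INDEX[DEAD]] = me
    M[i, STATE_INDEX[SURG_REMISSION]] = (1.0 - me) * pres
    M[i, STATE_INDEX[COMPLICATIONS]] = (1.0 - me) * (1.0 - pres)

    i = STATE_INDEX[SURG_REMISSION]
    M[i, STATE_INDEX[DEAD]] = m0  # 'no colectomy' mortality applied post-surgery
    M[i, STATE_INDEX[SURG_REMISSION]] = 1.0 - m0

    M[STATE_INDEX[DEAD], STATE_INDEX[DEAD]] = 1.0

    rowsums = M.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > _ROW_TOL) or np.any(M < -_ROW_TOL) or np.any(M > 1 + _ROW_TOL):
        raise ValidationError(f"invalid transition matrix at cycle {cycle}: row sums {rowsums}")
    return M


def run_cohort(
    initial_distribution, model: TransitionModel, horizon_cycles: int = 18
) -> CohortTrace:
    """Propagate the cohort: trace row t = row t-1 x matrix(t)."""
    x0 = np.asarray(initial_distribution, dtype=float)
    if x0.shape != (_N,):
        raise ValidationError(f"initial distribution must have {_N} entries")
    if abs(x0.sum() - 1.0) > 1e-9 or np.any(x0 < 0):
        raise ValidationError("initial distribution must be non-negative and sum to 1")
    if horizon_cycles > len(model.tp_colectomy):
        raise ValidationError(
            f"horizon {horizon_cycles} exceeds schedule length {len(model.tp_colectomy)}"
        )
    occ = np.zeros((horizon_cycles + 1, _N))
    occ[0] = x0
    surg_in = np.zeros(horizon_cycles)
    comp_in = np.zeros(horizon_cycles)
    m0 = model.annual_mortality_no_colectomy
    me = model.annual_mortality_emergency_colectomy
    pc = model.p_complication_given_surgery
    for t in range(1, horizon_cycles + 1):
        M = build_cycle_matrix(t, model)
        occ[t] = occ[t - 1] @ M
        q = model.tp_colectomy.tp(t)
        inflow = occ[t - 1, STATE_INDEX[REMISSION_MED]] * (1.0 - m0) * q
        inflow += occ[t - 1, STATE_INDEX[SURGERY]]  # any initial transient mass
        surg_in[t - 1] = inflow
        comp_in[t - 1] = inflow * (1.0 - me) * pc
    return CohortTrace(occupancy=occ, surgery_inflow=surg_in, complication_inflow=comp_in)


def discount_factors(horizon_cycles: int, rate: float, year_offset: int = 2) -> np.ndarray:
    """Per-cycle discount factors (1+r)**-(t + year_offset - 1), t = 1..H."""
    t = np.arange(1, horizon_cycles + 1)
    return (1.0 + rate) ** -(t + year_offset - 1)


def accumulate_payoffs(
    trace: CohortTrace,
    payoffs: PayoffTable,
    discount_rate: float = 0.035,
    year_offset: int = 2,
    cycle_length: float = 1.0,
    half_cycle_correction: bool = False,
    arm: str = "",
) -> MMResult:
    """Discounted cost and QALY totals over the cohort trace.

    State payoffs are applied to end-of-cycle occupancy (with the optional
    half-cycle correction, to the mean of start and end occupancy); one-off
    surgery/complication payoffs apply to the inflow mass in the cycle of
    entry, at the same cycle's discount factor.
    """
    H = trace.n_cycles
    try:
        u = np.array([payoffs.utilities[s] for s in states.PAYOFF_STATES])
        c = np.array([payoffs.annual_costs[s] for s in states.PAYOFF_STATES])
    except KeyError as exc:
        raise ValidationError(f"missing payoff for state {exc.args[0]!r}") from exc
    idx = [STATE_INDEX[s] for s in states.PAYOFF_STATES]
    occ = trace.occupancy[1:, idx]
    if half_cycle_correction:
        occ = 0.5 * (occ + trace.occupancy[:-1, idx])
    df = discount_factors(H, discount_rate, year_offset)
    qaly = float(df @ (occ @ u) * cycle_length)
    cost = float(df @ (occ @ c) * cycle_length)
    surg_cost = payoffs.one_off_costs.get("surgery", 0.0)
    comp_cost = payoffs.one_off_costs.get("complication", 0.0)
    surg_du = payoffs.one_off_utility_decrements.get("surgery", 0.0)
    comp_du = payoffs.one_off_utility_decrements.get("complication", 0.0)
    cost += float(df @ (trace.surgery_inflow * surg_cost + trace.complication_inflow * comp_cost))
    qaly -= float(df @ (trace.surgery_inflow * surg_du + trace.complication_inflow * comp_du))
    return MMResult(arm=arm, discounted_cost=cost, discounted_qaly=qaly, trace=trace)


def microsimulate(
    n_patients: int,
    model: TransitionModel,
    payoffs: PayoffTable,
    horizon_cycles: int = 18,
    seed: int | np.random.Generator = 0,
    discount_rate: float = 0.035,
    year_offset: int = 2,
    initial_state: str = REMISSION_MED,
) -> MMResult:
    """Individual-level rollout of the same dynamics (cohort-engine oracle).

    Each patient's trajectory is sampled with the same event sequencing as
    the cohort matrices (background death, then colectomy, then surgical
    death, then complications); mean discounted payoffs are reported with
    Monte-Carlo standard errors.
    """
    if n_patients < 1:
        raise ValidationError("need n_patients >= 1")
    problems = model.validate()
    if problems:
        raise ValidationError(problems)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m0 = model.annual_mortality_no_colectomy
    me = model.annual_mortality_emergency_colectomy
    pc = model.p_complication_given_surgery
    pres = model.p_complication_resolution
    u = {s: payoffs.utilities[s] for s in states.PAYOFF_STATES}
    cst = {s: payoffs.annual_costs[s] for s in states.PAYOFF_STATES}
    surg_cost = payoffs.one_off_costs.get("surgery", 0.0)
    comp_cost = payoffs.one_off_costs.get("complication", 0.0)
    surg_du = payoffs.one_off_utility_decrements.get("surgery", 0.0)
    comp_du = payoffs.one_off_utility_decrements.get("complication", 0.0)

    state = np.full(n_patients, STATE_INDEX[initial_state], dtype=int)
    qaly = np.zeros(n_patients)
    cost = np.zeros(n_patients)
    dfs = discount_factors(horizon_cycles, discount_rate, year_offset)
    iREM, iSUR, iCMP, iSRM, iDED = (STATE_INDEX[s] for s in STATES)

    for t in range(1, horizon_cycles + 1):
        df = dfs[t - 1]
        q = model.tp_colectomy.tp(t)
        new = state.copy()

        rem = state == iREM
        die_bg = rem & (rng.random(n_patients) < m0)
        new[die_bg] = iDED
        go_surg = rem & ~die_bg & (rng.random(n_patients) < q)
        # patients starting a cycle in the transient surgery state (only
        # possible via a degenerate initial distribution) also resolve now
        go_surg |= state == iSUR

        die_surg = go_surg & (rng.random(n_patients) < me)
        compl = go_surg & ~die_surg & (rng.random(n_patients) < pc)
        new[go_surg] = iSRM
        new[die_surg] = iDED
        new[compl] = iCMP
        cost[go_surg] += surg_cost * df
        qaly[go_surg] -= surg_du * df
        cost[compl] += comp_cost * df
        qaly[compl] -= comp_du * df

        cmp_now = state == iCMP
        die_cmp = cmp_now & (rng.random(n_patients) < me)
        resolve = cmp_now & ~die_cmp & (rng.random(n_patients) < pres)
        new[die_cmp] = iDED
        new[resolve] = iSRM

        srm = state == iSRM
        die_srm = srm & (rng.random(n_patients) < m0)
        new[die_srm] = iDED

        state = new
        for s, i in ((REMISSION_MED, iREM), (COMPLICATIONS, iCMP),
                     (SURG_REMISSION, iSRM), (DEAD, iDED)):
            mask = state == i
            qaly[mask] += u[s] * df
            cost[mask] += cst[s] * df

    se = lambda x: float(np.std(x, ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0
    return MMResult(
        arm="microsim",
        discounted_cost=float(cost.mean()),
        discounted_qaly=float(qaly.mean()),
        trace=None,
        se_cost=se(cost),
        se_qaly=se(qaly),
    )
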