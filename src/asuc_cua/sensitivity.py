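"""Deterministic scenario analyses and probabilistic sensitivity analysis.

The deterministic engine re-runs the full decision-tree + Markov pipeline
with exactly one modification at a time: infliximab (biosimilar) price
reductions, +/-10% changes in either arm's utilities, a 10-year horizon,
and a fixed annual colectomy transition probability (defaults 0.07
infliximab / 0.10 ciclosporin) in place of the Weibull schedule.

The PSA draws every uncertain input independently per iteration — Beta
distributions for utilities, Weibull lambda and gamma, and mortality
probabilities; Gamma for state costs — rebuilds the transition schedules,
re-runs both arms, and records the incremental (cost, QALY) pair.  Results
feed a cost-effectiveness plane and a cost-effectiveness acceptability
curve (probability that the comparator is cost-effective as a function of
the willingness-to-pay threshold; ties at zero net benefit count as not
cost-effective).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import PSAConfig
from .distributions import beta_from_moments, gamma_from_moments
from .errors import ValidationError
from .pipeline import BaseCaseResult, ModelInputs, run_base_case
from .states import DEAD
from .synth import PayoffTable

# re-exported for callers configuring the PSA
__all__ = [
    "ScenarioSpec", "default_scenarios", "run_scenario", "run_scenarios",
    "PSAResult", "run_psa", "ceac", "beta_from_moments", "gamma_from_moments",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One deterministic one-way scenario."""

    label: str
    infliximab_price_multiplier: float = 1.0
    utility_multiplier: dict = field(default_factory=dict)  # arm -> factor
    horizon_years: int | None = None  # None = base-case horizon
    tp_mode: str = "weibull_time_dependent"

    def validate(self) -> list[str]:
        problems = []
        if self.infliximab_price_multiplier <= 0:
            problems.append(f"{self.label}: price multiplier must be > 0")
        for arm, m in self.utility_multiplier.items():
            if m <= 0:
                problems.append(f"{self.label}: utility multiplier for {arm} must be > 0")
        if self.tp_mode not in ("weibull_time_dependent", "fixed"):
            problems.append(f"{self.label}: unknown tp_mode {self.tp_mode!r}")
        if self.horizon_years is not None and self.horizon_years < 3:
            problems.append(f"{self.label}: horizon_years must be >= 3")
        return problems


def default_scenarios() -> list[ScenarioSpec]:
    """The twelve shipped one-way scenarios."""
    out = [
        ScenarioSpec(f"{int(red * 100)}% reduction in infliximab price",
                     infliximab_price_multiplier=1.0 - red)
        for red in (0.10, 0.20, 0.50, 0.70, 0.80)
    ]
    for arm in ("ciclosporin", "infliximab"):
        for delta, word in ((-0.10, "reduction"), (0.10, "increase")):
            out.append(
                ScenarioSpec(
                    f"10% {word} in {arm} utility",
                    utility_multiplier={arm: 1.0 + delta},
                )
            )
    out.append(ScenarioSpec("Fixed transition probability", tp_mode="fixed"))
    out.append(ScenarioSpec("10-year time horizon (time-dependent TP)", horizon_years=10))
    out.append(
        ScenarioSpec("10-year time horizon (fixed TP)", horizon_years=10, tp_mode="fixed")
    )
    return out


def run_scenario(inputs: ModelInputs, scenario: ScenarioSpec) -> BaseCaseResult:
    """Re-run the full pipeline with exactly the scenario's modification."""
    problems = scenario.validate()
    if problems:
        raise ValidationError(problems)
    per_arm = {
        arm: {"utility_multiplier": m} for arm, m in scenario.utility_multiplier.items()
    }
    return run_base_case(
        inputs,
        price_multiplier=scenario.infliximab_price_multiplier,
        horizon_years=scenario.horizon_years,
        tp_mode=scenario.tp_mode,
        per_arm=per_arm,
    )


def run_scenarios(
    inputs: ModelInputs, scenarios: list[ScenarioSpec] | None = None
) -> pd.DataFrame:
    """Scenario table (one row per scenario, base case first)."""
    if scenarios is None:
        scenarios = default_scenarios()
    rows = []
    base = run_base_case(inputs)
    for label, res in [("Base case", base)] + [
        (sc.label, run_scenario(inputs, sc)) for sc in scenarios
    ]:
        rows.append(
            {
                "scenario": label,
                "cost_infliximab": res.reference.combined.cost,
                "qaly_infliximab": res.reference.combined.qaly,
                "cost_ciclosporin": res.comparator.combined.cost,
                "qaly_ciclosporin": res.comparator.combined.qaly,
                "incremental_qaly": res.comparison.delta_qaly,
                "incremental_cost": res.comparison.delta_cost,
                "icer": res.comparison.icer,
                "cost_effectiveness": res.comparison.classification,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Per-draw incremental pairs (comparator minus reference)."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    n_draws: int

    def mean_comparison(self) -> tuple[float, float]:
        return float(self.delta_cost.mean()), float(self.delta_qaly.mean())

    def ce_plane_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_qaly": self.delta_qaly, "delta_cost": self.delta_cost}
        )


def _validate_psa_feasibility(inputs: ModelInputs, psa: PSAConfig) -> None:
    """Fail fast: every Beta/Gamma parameterisation must be feasible."""
    problems = []
    for arm, ai in inputs.arms.items():
        wu = psa.weibull.get(arm)
        if wu is None:
            problems.append(f"psa.weibull missing arm {arm!r}")
            continue
        for name, mean, se in (
            ("shape", ai.weibull_shape, wu.shape_se),
            ("scale", ai.weibull_scale, wu.scale_se),
        ):
            if se == 0.0:
                continue
            try:
                beta_from_moments(mean, se)
            except ValidationError as exc:
                problems.append(
                    f"psa weibull {name} for {arm}: {exc} "
                    "(a Beta draw needs mean in (0,1); consider a Gamma fallback)"
                )
        for state, u in ai.base_payoffs.utilities.items():
            if state == DEAD or psa.utility_se == 0.0 or u <= 0.0 or u >= 1.0:
                continue
            try:
                beta_from_moments(u, psa.utility_se)
            except ValidationError as exc:
                problems.append(f"psa utility for {arm}/{state}: {exc}")
    for name, m in (
        ("mortality_no_colectomy", inputs.mortality_no_colectomy_annual),
        ("mortality_emergency", inputs.mortality_emergency_annual),
    ):
        if psa.mortality_se > 0.0 and 0.0 < m < 1.0:
            try:
                beta_from_moments(m, psa.mortality_se)
            except ValidationError as exc:
                problems.append(f"psa {name}: {exc}")
    if problems:
        raise ValidationError(problems)


def _draw_beta(rng, mean, se):
    if se == 0.0 or not 0.0 < mean < 1.0:
        return mean
    a, b = beta_from_moments(mean, se)
    return float(rng.beta(a, b))


def _draw_payoffs(rng, table: PayoffTable, utility_se: float, cost_se_fraction: float
                  ) -> PayoffTable:
    def cost_draw(c):
        if cost_se_fraction == 0.0 or c <= 0.0:
            return c
        shape, scale = gamma_from_moments(c, cost_se_fraction * c)
        return float(rng.gamma(shape, scale))

    return replace(
        table,
        utilities={
            s: (0.0 if s == DEAD else _draw_beta(rng, u, utility_se))
            for s, u in table.utilities.items()
        },
        annual_costs={s: cost_draw(c) for s, c in table.annual_costs.items()},
        one_off_costs={ev: cost_draw(c) for ev, c in table.one_off_costs.items()},
    )


def run_psa(inputs: ModelInputs, psa: PSAConfig) -> PSAResult:
    """Monte-Carlo PSA: ``psa.n_draws`` re-evaluations of both arms.

    Per draw, utilities / costs / Weibull (lambda, gamma) / mortality are
    sampled independently from their moment-matched distributions, the
    transition schedules are rebuilt from the drawn Weibull parameters, and
    the full DT+MM pipeline is re-run.  Deterministic given ``psa.seed``.
    """
    problems = psa.validate()
    if problems:
        raise ValidationError(problems)
    _validate_psa_feasibility(inputs, psa)
    rng = np.random.default_rng(psa.seed)
    n = psa.n_draws
    dc = np.empty(n)
    de = np.empty(n)
    for i in range(n):
        per_arm = {}
        m0 = _draw_beta(rng, inputs.mortality_no_colectomy_annual, psa.mortality_se)
        me = _draw_beta(rng, inputs.mortality_emergency_annual, psa.mortality_se)
        for arm, ai in inputs.arms.items():
            wu = psa.weibull[arm]
            shape = _draw_beta(rng, ai.weibull_shape, wu.shape_se)
            scale = _draw_beta(rng, ai.weibull_scale, wu.scale_se)
            per_arm[arm] = {
                "weibull": (shape, scale),
                "base_payoffs": _draw_payoffs(
                    rng, ai.base_payoffs, psa.utility_se, psa.cost_se_fraction
                ),
                "mortality": (m0, me),
            }
        res = run_base_case(inputs, per_arm=per_arm)
        dc[i] = res.comparison.delta_cost
        de[i] = res.comparison.delta_qaly
    return PSAResult(delta_cost=dc, delta_qaly=de, seed=psa.seed, n_draws=n)


def ceac(psa_result: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for the comparator.

    At each threshold, the fraction of draws with positive net monetary
    benefit wtp * dQALY - dCost (ties count as not cost-effective).
    """
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 50_001.0, 500.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValidationError("empty willingness-to-pay grid")
    nmb = wtp_grid[:, None] * psa_result.delta_qaly[None, :] - psa_result.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp_grid, "probability_cost_effective": prob})


def probability_cost_effective(psa_result: PSAResult, wtp: float) -> float:
    """CEAC value at a single threshold."""
    nmb = wtp * psa_result.delta_qaly - psa_result.delta_cost
    return float((nmb > 0).mean())


def plot_ce_plane(psa_result: PSAResult, path, wtp: float | None = None) -> None:
    """Scatter of incremental (QALY, cost) pairs; optional WTP ray."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa_result.delta_qaly, psa_result.delta_cost, s=4, alpha=0.3)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    if wtp is not None:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, wtp * xs, color="red", lw=0.8, label=f"WTP = {wtp:,.0f}/QALY")
        ax.legend()
    ax.set_xlabel("Incremental QALYs (ciclosporin - infliximab)")
    ax.set_ylabel("Incremental cost, GBP")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["probability_cost_effective"])
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness-to-pay threshold, GBP/QALY")
    ax.set_ylabel("P(ciclosporin cost-effective)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
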