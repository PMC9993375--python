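"""YAML configuration: schema, validation and round-tripping.

A single YAML file drives the whole pipeline: the synthetic cohort
specification, survival-model settings, decision-tree parameters per arm,
state payoffs per arm, Markov inputs (mortality as published multi-year
probabilities, converted to annual inside the pipeline), economic settings,
the deterministic scenario list and the PSA configuration.

Validation collects *all* invariant violations before raising, so a broken
config reports every problem at once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError
from .synth import ArmSpec, ARMS, CohortSpec, PayoffTable, WeibullEventModel

DEFAULT_CONFIG_RESOURCE = "default_config.yaml"


def default_config_path() -> Path:
    """Path of the shipped base-case configuration."""
    return Path(resources.files("asuc_cua").joinpath("data", DEFAULT_CONFIG_RESOURCE))


@dataclass(frozen=True)
class SurvivalConfig:
    families: tuple[str, ...] = ("weibull", "exponential", "gompertz", "loglogistic")
    covariates: tuple[str, ...] = ("age_at_randomisation", "weight")
    covariate_profile: str = "means"  # schedules at covariate means, or "zero"

    def validate(self) -> list[str]:
        from .survival import FAMILIES

        problems = []
        for f in self.families:
            if f not in FAMILIES:
                problems.append(f"survival.families: unknown family {f!r}")
        if "weibull" not in self.families:
            problems.append("survival.families must include 'weibull'")
        if self.covariate_profile not in ("means", "zero"):
            problems.append(
                f"survival.covariate_profile must be 'means' or 'zero'; "
                f"got {self.covariate_profile!r}"
            )
        return problems


@dataclass(frozen=True)
class ArmDTConfig:
    """Decision-tree branch probabilities and drug cost for one arm."""

    p_initial_remission: float
    p_colectomy_mid: float
    p_colectomy_late: float
    p_postop_complication: float
    p_death_surgery: float
    drug_cost_initial: float

    def validate(self, prefix: str) -> list[str]:
        problems = []
        for name in (
            "p_initial_remission", "p_colectomy_mid", "p_colectomy_late",
            "p_postop_complication", "p_death_surgery",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{prefix}.{name}={v} outside [0, 1]")
        if self.p_postop_complication + self.p_death_surgery > 1.0:
            problems.append(f"{prefix}: complication + surgical death probabilities exceed 1")
        if self.drug_cost_initial < 0:
            problems.append(f"{prefix}.drug_cost_initial must be >= 0")
        return problems


@dataclass(frozen=True)
class ArmPayoffConfig:
    """State payoffs for one arm; drug cost kept separate from state costs
    so price scenarios rescale exactly the drug components."""

    payoffs: PayoffTable
    annual_drug_cost_remission: float = 0.0

    def validate(self, prefix: str) -> list[str]:
        problems = self.payoffs.validate(prefix)
        if self.annual_drug_cost_remission < 0:
            problems.append(f"{prefix}.annual_drug_cost_remission must be >= 0")
        return problems


@dataclass(frozen=True)
class MortalityConfig:
    """Published mortality probabilities over ``period_years``, by pathway."""

    no_colectomy: float
    emergency_colectomy: float
    period_years: float = 3.0

    def validate(self, prefix: str = "markov.mortality") -> list[str]:
        problems = []
        for name in ("no_colectomy", "emergency_colectomy"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                problems.append(f"{prefix}.{name}={v} outside [0, 1)")
        if self.period_years <= 0:
            problems.append(f"{prefix}.period_years must be > 0")
        return problems


@dataclass(frozen=True)
class MarkovConfig:
    p_complication_given_surgery: float
    mortality: MortalityConfig
    p_complication_resolution: float = 1.0
    half_cycle_correction: bool = False
    fixed_tp: dict = field(default_factory=lambda: {"infliximab": 0.07, "ciclosporin": 0.10})

    def validate(self) -> list[str]:
        problems = []
        for name in ("p_complication_given_surgery", "p_complication_resolution"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"markov.{name}={v} outside [0, 1]")
        for arm, tp in self.fixed_tp.items():
            if not 0.0 <= tp <= 1.0:
                problems.append(f"markov.fixed_tp[{arm}]={tp} outside [0, 1]")
        problems += self.mortality.validate()
        return problems


@dataclass(frozen=True)
class EconomicsConfig:
    discount_rate: float = 0.035
    wtp: float = 20_000.0
    horizon_years: int = 20
    price_year: int = 2019
    inflation_multiplier: float = 1.0  # applied by the user upstream; metadata here

    def validate(self) -> list[str]:
        problems = []
        if self.discount_rate < 0:
            problems.append(f"economics.discount_rate must be >= 0; got {self.discount_rate}")
        if self.wtp <= 0:
            problems.append(f"economics.wtp must be > 0; got {self.wtp}")
        if self.horizon_years < 3:
            problems.append(
                f"economics.horizon_years must exceed the 2-year tree; got {self.horizon_years}"
            )
        if self.inflation_multiplier <= 0:
            problems.append("economics.inflation_multiplier must be > 0")
        return problems


@dataclass(frozen=True)
class WeibullUncertainty:
    shape_se: float = 0.047
    scale_se: float = 0.03

    def validate(self, prefix: str) -> list[str]:
        problems = []
        for name in ("shape_se", "scale_se"):
            if getattr(self, name) < 0:
                problems.append(f"{prefix}.{name} must be >= 0")
        return problems


@dataclass(frozen=True)
class PSAConfig:
    """Probabilistic sensitivity analysis settings.

    Utilities, Weibull shape/scale and mortality probabilities are drawn
    from moment-matched Beta distributions; state costs from Gamma
    distributions with SE = ``cost_se_fraction`` x mean.
    """

    n_draws: int = 10_000
    seed: int = 1
    utility_se: float = 0.05
    cost_se_fraction: float = 0.2
    mortality_se: float = 0.005
    weibull: dict = field(
        default_factory=lambda: {
            "infliximab": WeibullUncertainty(),
            "ciclosporin": WeibullUncertainty(),
        }
    )

    def validate(self) -> list[str]:
        problems = []
        if self.n_draws < 1:
            problems.append(f"psa.n_draws must be >= 1; got {self.n_draws}")
        for name in ("utility_se", "cost_se_fraction", "mortality_se"):
            if getattr(self, name) < 0:
                problems.append(f"psa.{name} must be >= 0")
        for arm, wu in self.weibull.items():
            problems += wu.validate(f"psa.weibull[{arm}]")
        return problems


@dataclass(frozen=True)
class ScenarioConfigEntry:
    """Raw scenario entry; resolved to a ScenarioSpec by the sensitivity module."""

    label: str
    infliximab_price_multiplier: float = 1.0
    utility_multiplier: dict = field(default_factory=dict)
    horizon_years: int | None = None
    tp_mode: str = "weibull_time_dependent"

    def validate(self, prefix: str) -> list[str]:
        problems = []
        if self.infliximab_price_multiplier <= 0:
            problems.append(f"{prefix}.infliximab_price_multiplier must be > 0")
        for arm, m in self.utility_multiplier.items():
            if m <= 0:
                problems.append(f"{prefix}.utility_multiplier[{arm}] must be > 0")
        if self.tp_mode not in ("weibull_time_dependent", "fixed"):
            problems.append(f"{prefix}.tp_mode must be 'weibull_time_dependent' or 'fixed'")
        return problems


@dataclass(frozen=True)
class RunConfig:
    synthetic: CohortSpec
    survival: SurvivalConfig
    decision_tree: dict  # arm -> ArmDTConfig
    payoffs: dict  # arm -> ArmPayoffConfig
    markov: MarkovConfig
    economics: EconomicsConfig
    psa: PSAConfig
    scenarios: list | str = "default"  # "default" or list[ScenarioConfigEntry]

    def validate(self) -> list[str]:
        problems = self.synthetic.validate()
        problems += self.survival.validate()
        for section_name, section in (("decision_tree", self.decision_tree),
                                      ("payoffs", self.payoffs)):
            for arm in ARMS:
                if arm not in section:
                    problems.append(f"{section_name} missing arm {arm!r}")
        for arm, dt in self.decision_tree.items():
            problems += dt.validate(f"decision_tree.{arm}")
        for arm, pc in self.payoffs.items():
            problems += pc.validate(f"payoffs.{arm}")
        problems += self.markov.validate()
        problems += self.economics.validate()
        problems += self.psa.validate()
        if isinstance(self.scenarios, list):
            for i, sc in enumerate(self.scenarios):
                problems += sc.validate(f"scenarios[{i}]")
        elif self.scenarios != "default":
            problems.append("scenarios must be 'default' or a list")
        return problems


# ---------------------------------------------------------------------------
# YAML <-> dataclass plumbing
# ---------------------------------------------------------------------------


def _cohort_from_dict(d: dict) -> CohortSpec:
    arms = {}
    for arm, a in d.get("arms", {}).items():
        em = a.get("event_model", {})
        arms[arm] = ArmSpec(
            n=int(a["n"]),
            age_mean=float(a["age_mean"]),
            age_sd=float(a["age_sd"]),
            weight_mean=float(a["weight_mean"]),
            weight_sd=float(a["weight_sd"]),
            event_model=WeibullEventModel(
                shape=float(em["shape"]),
                scale=float(em["scale"]),
                beta_age=float(em.get("beta_age", 0.0)),
                beta_weight=float(em.get("beta_weight", 0.0)),
            ),
        )
    return CohortSpec(
        arms=arms,
        censor_time=float(d.get("censor_time_years", 2.0)),
        seed=int(d.get("seed", 0)),
    )


def _payoffs_from_dict(d: dict) -> ArmPayoffConfig:
    table = PayoffTable(
        utilities={k: float(v) for k, v in d.get("utilities", {}).items()},
        annual_costs={k: float(v) for k, v in d.get("annual_costs", {}).items()},
        one_off_costs={k: float(v) for k, v in d.get("one_off_costs", {}).items()},
        one_off_utility_decrements={
            k: float(v) for k, v in d.get("one_off_utility_decrements", {}).items()
        },
    )
    return ArmPayoffConfig(
        payoffs=table,
        annual_drug_cost_remission=float(d.get("annual_drug_cost_remission", 0.0)),
    )


def config_from_dict(raw: dict) -> RunConfig:
    missing = [s for s in ("synthetic", "decision_tree", "payoffs", "markov", "economics")
               if s not in raw]
    if missing:
        raise ValidationError([f"missing config section {s!r}" for s in missing])
    surv = raw.get("survival", {})
    mk = raw["markov"]
    mort = mk.get("mortality", {})
    psa_raw = raw.get("psa", {})
    weib_unc = {
        arm: WeibullUncertainty(
            shape_se=float(w.get("shape_se", 0.047)), scale_se=float(w.get("scale_se", 0.03))
        )
        for arm, w in psa_raw.get("weibull", {}).items()
    } or PSAConfig().weibull
    scenarios_raw = raw.get("scenarios", "default")
    if isinstance(scenarios_raw, list):
        scenarios = [
            ScenarioConfigEntry(
                label=s["label"],
                infliximab_price_multiplier=float(s.get("infliximab_price_multiplier", 1.0)),
                utility_multiplier={k: float(v) for k, v in s.get("utility_multiplier", {}).items()},
                horizon_years=s.get("horizon_years"),
                tp_mode=s.get("tp_mode", "weibull_time_dependent"),
            )
            for s in scenarios_raw
        ]
    else:
        scenarios = scenarios_raw

    cfg = RunConfig(
        synthetic=_cohort_from_dict(raw["synthetic"]),
        survival=SurvivalConfig(
            families=tuple(surv.get("families", SurvivalConfig().families)),
            covariates=tuple(surv.get("covariates", SurvivalConfig().covariates)),
            covariate_profile=surv.get("covariate_profile", "means"),
        ),
        decision_tree={
            arm: ArmDTConfig(**{k: float(v) for k, v in d.items()})
            for arm, d in raw["decision_tree"].items()
        },
        payoffs={arm: _payoffs_from_dict(d) for arm, d in raw["payoffs"].items()},
        markov=MarkovConfig(
            p_complication_given_surgery=float(mk["p_complication_given_surgery"]),
            p_complication_resolution=float(mk.get("p_complication_resolution", 1.0)),
            half_cycle_correction=bool(mk.get("half_cycle_correction", False)),
            fixed_tp={k: float(v) for k, v in mk.get("fixed_tp",
                      {"infliximab": 0.07, "ciclosporin": 0.10}).items()},
            mortality=MortalityConfig(
                no_colectomy=float(mort["no_colectomy"]),
                emergency_colectomy=float(mort["emergency_colectomy"]),
                period_years=float(mort.get("period_years", 3.0)),
            ),
        ),
        economics=EconomicsConfig(**raw["economics"]),
        psa=PSAConfig(
            n_draws=int(psa_raw.get("n_draws", 10_000)),
            seed=int(psa_raw.get("seed", 1)),
            utility_se=float(psa_raw.get("utility_se", 0.05)),
            cost_se_fraction=float(psa_raw.get("cost_se_fraction", 0.2)),
            mortality_se=float(psa_raw.get("mortality_se", 0.005)),
            weibull=weib_unc,
        ),
        scenarios=scenarios,
    )
    problems = cfg.validate()
    if problems:
        raise ValidationError(problems)
    return cfg


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} did not parse to a mapping")
    return config_from_dict(raw)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    """Plain-dict form of a config, loadable again by ``config_from_dict``."""
    d = _to_plain(cfg)
    # restore the YAML field names that differ from dataclass internals
    synth = d["synthetic"]
    synth["censor_time_years"] = synth.pop("censor_time")
    d["payoffs"] = {
        arm: {**p.pop("payoffs"), **p} for arm, p in d["payoffs"].items()
    }
    if isinstance(cfg.scenarios, str):
        d["scenarios"] = cfg.scenarios
    return d


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
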