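"""End-to-end pipeline runner: synth -> fit -> DT -> MM -> CEA -> SA -> PSA.

Writes every stage's outputs (CSV/JSON) to an output directory together
with a manifest recording seeds, package versions and stage runtimes, so a
run is fully reproducible from its config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cea import results_table
from .config import RunConfig, config_to_dict, default_config_path, load_config
from .errors import FitError
from .pipeline import build_inputs, run_base_case
from .sensitivity import (
    ceac,
    default_scenarios,
    plot_ce_plane,
    plot_ceac,
    probability_cost_effective,
    run_psa,
    run_scenarios,
    ScenarioSpec,
)
from .survival import compare_fits, fit_parametric, tp_schedule_from_weibull
from .synth import generate_cohort

log = logging.getLogger("asuc_cua")


def _versions() -> dict:
    import lifelines
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "lifelines": lifelines.__version__,
    }


def fit_survival_models(config: RunConfig, records: pd.DataFrame) -> dict:
    """Fit every configured family per arm; returns
    {arm: {"fits": {family: fit}, "comparison": DataFrame, "weibull": fit}}."""
    out = {}
    for arm in config.decision_tree:
        arm_records = records[records["arm"] == arm]
        fits = {}
        for family in config.survival.families:
            try:
                fits[family] = fit_parametric(
                    arm_records, family=family, covariate_names=config.survival.covariates
                )
            except FitError as exc:  # keep going: comparison table just shrinks
                log.warning("fit of %s for %s failed: %s", family, arm, exc)
        if "weibull" not in fits:
            raise FitError(f"weibull fit failed for arm {arm}")
        out[arm] = {
            "fits": fits,
            "comparison": compare_fits(list(fits.values())),
            "weibull": fits["weibull"],
        }
    return out


def _scenarios_from_config(config: RunConfig):
    if config.scenarios == "default":
        return default_scenarios()
    return [
        ScenarioSpec(
            label=e.label,
            infliximab_price_multiplier=e.infliximab_price_multiplier,
            utility_multiplier=dict(e.utility_multiplier),
            horizon_years=e.horizon_years,
            tp_mode=e.tp_mode,
        )
        for e in config.scenarios
    ]


def run_all(
    config: RunConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    skip_psa: bool = False,
    plots: bool = False,
) -> dict:
    """Execute the full pipeline; returns the manifest of written artifacts.

    ``seed`` overrides the config's synthetic seed and (shifted) PSA seed,
    giving end-to-end determinism from a single integer.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config) if config else load_config(default_config_path())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": {}, "runtimes_s": {}, "versions": _versions()}
    t_all = time.time()

    if seed is not None:
        ss = np.random.SeedSequence(seed)
        synth_seed, psa_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
        from dataclasses import replace

        config = replace(
            config,
            synthetic=replace(config.synthetic, seed=synth_seed),
            psa=replace(config.psa, seed=psa_seed),
        )
    manifest["seeds"] = {"synthetic": config.synthetic.seed, "psa": config.psa.seed}

    def stage(name):
        manifest["runtimes_s"][name] = round(time.time() - t_stage[0], 3)
        t_stage[0] = time.time()

    def artifact(name, path):
        manifest["artifacts"][name] = str(path)

    t_stage = [time.time()]

    # 1. synthetic cohort
    records = generate_cohort(config.synthetic)
    patients_csv = out_dir / "patients.csv"
    records.to_csv(patients_csv, index=False)
    artifact("patients", patients_csv)
    stage("synth")

    # 2. survival fits
    fits = fit_survival_models(config, records)
    weibull_params = {}
    for arm, info in fits.items():
        info["comparison"].to_csv(out_dir / f"fit_comparison_{arm}.csv", index=False)
        artifact(f"fit_comparison_{arm}", out_dir / f"fit_comparison_{arm}.csv")
        info["weibull"].to_json(out_dir / f"weibull_fit_{arm}.json")
        artifact(f"weibull_fit_{arm}", out_dir / f"weibull_fit_{arm}.json")
        weibull_params[arm] = (info["weibull"].shape, info["weibull"].scale)
        profile = None  # fit centering profile = covariate means
        if config.survival.covariate_profile == "zero":
            profile = {c: 0.0 for c in config.survival.covariates}
        sched = tp_schedule_from_weibull(
            info["weibull"], covariate_profile=profile,
            horizon_cycles=config.economics.horizon_years - 2,
        )
        sched.to_csv(out_dir / f"tp_schedule_{arm}.csv")
        artifact(f"tp_schedule_{arm}", out_dir / f"tp_schedule_{arm}.csv")
    stage("fit")

    # 3-5. decision tree, Markov, combined CEA
    inputs = build_inputs(config, weibull_params)
    base = run_base_case(inputs)
    for ev in (base.reference, base.comparator):
        ev.dt.path_table.to_csv(out_dir / f"dt_paths_{ev.arm}.csv", index=False)
        artifact(f"dt_paths_{ev.arm}", out_dir / f"dt_paths_{ev.arm}.csv")
        ev.mm.trace.to_csv(out_dir / f"markov_trace_{ev.arm}.csv")
        artifact(f"markov_trace_{ev.arm}", out_dir / f"markov_trace_{ev.arm}.csv")
    table = results_table(base.reference.combined, base.comparator.combined, base.comparison)
    component_rows = pd.DataFrame(
        [
            {
                "scenario": "decision_tree_2yr",
                "cost_infliximab": base.reference.dt.expected_cost,
                "qaly_infliximab": base.reference.dt.expected_qaly,
                "cost_ciclosporin": base.comparator.dt.expected_cost,
                "qaly_ciclosporin": base.comparator.dt.expected_qaly,
            },
            {
                "scenario": "markov_18yr",
                "cost_infliximab": base.reference.mm.discounted_cost,
                "qaly_infliximab": base.reference.mm.discounted_qaly,
                "cost_ciclosporin": base.comparator.mm.discounted_cost,
                "qaly_ciclosporin": base.comparator.mm.discounted_qaly,
            },
        ]
    )
    results = pd.concat([component_rows, table], ignore_index=True)
    results.to_csv(out_dir / "results_table.csv", index=False)
    artifact("results_table", out_dir / "results_table.csv")
    stage("base_case")

    # 6. deterministic scenarios
    scen_table = run_scenarios(inputs, _scenarios_from_config(config))
    scen_table.to_csv(out_dir / "scenarios.csv", index=False)
    artifact("scenarios", out_dir / "scenarios.csv")
    stage("scenarios")

    # 7. PSA
    if not skip_psa:
        psa_result = run_psa(inputs, config.psa)
        psa_result.ce_plane_frame().to_csv(out_dir / "psa_ce_plane.csv", index=False)
        artifact("psa_ce_plane", out_dir / "psa_ce_plane.csv")
        curve = ceac(psa_result)
        curve.to_csv(out_dir / "psa_ceac.csv", index=False)
        artifact("psa_ceac", out_dir / "psa_ceac.csv")
        manifest["psa_probability_cost_effective_at_wtp"] = probability_cost_effective(
            psa_result, inputs.wtp
        )
        if plots:
            plot_ce_plane(psa_result, out_dir / "psa_ce_plane.png", wtp=inputs.wtp)
            artifact("psa_ce_plane_png", out_dir / "psa_ce_plane.png")
            plot_ceac(curve, out_dir / "psa_ceac.png")
            artifact("psa_ceac_png", out_dir / "psa_ceac.png")
        stage("psa")

    manifest["config"] = config_to_dict(config)
    manifest["runtimes_s"]["total"] = round(time.time() - t_all, 3)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    artifact("manifest", out_dir / "manifest.json")
    return manifest
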