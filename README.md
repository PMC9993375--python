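# asuc-cua

Model-based cost-utility analysis of rescue therapy — infliximab versus
ciclosporin — for steroid-resistant acute severe ulcerative colitis (ASUC),
from the UK NHS perspective.

About a third of hospitalised ASUC patients do not respond to intravenous
steroids; the two rescue drugs are similarly effective at preventing
emergency colectomy but differ sharply in price.  This package implements
the standard two-stage decision-analytic design for that question, as a
tested, reusable Python pipeline for health economists:

- a **2-year decision tree** (three periods: 0–3, 4–12, 13–24 months) in
  which patients achieve remission or fail to colectomy, with surgical
  complications and perioperative death;
- an **18-year annual-cycle Markov cohort model** (remission on medical
  therapy → surgery → complications / surgical remission → dead) whose
  colectomy transition follows a time-dependent schedule
  tp(t) = 1 − S(t)/S(t−1) derived from a proportional-hazards Weibull
  regression h(t|x) = λγt^{γ−1}e^{x'β} fitted to censored two-year
  time-to-colectomy data (exponential, Gompertz and log-logistic
  alternatives compared by AIC/BIC);
- **incremental cost-effectiveness**: ΔC, ΔQALY, dominance classification
  or ICER, and net monetary benefit at the £20,000/QALY NICE threshold,
  with 3.5% annual discounting beyond the first 12 months;
- **twelve one-way deterministic scenarios** (biosimilar price reductions,
  ±10% utilities, fixed transition probabilities 0.07/0.10, 10-year
  horizon) and a **10,000-draw probabilistic sensitivity analysis** (Beta
  utilities/Weibull parameters/mortality, Gamma costs) producing a CE
  plane and a cost-effectiveness acceptability curve (CEAC).

Patient-level trial data are access-restricted, so the package ships a
**synthetic trial generator** reproducing the published cohort statistics
and Weibull event-time structure, plus clearly-labelled synthetic state
payoffs.  Absolute totals are therefore illustrative; the published
*qualitative* result (ciclosporin cheaper and more effective — dominant —
with high probability of cost-effectiveness) is reproduced, and the
machinery is exact.  See `docs/methods.md` for the model, assumptions and
limitations.

## Worked example

```sh
asuc-cua run-all --seed 1 --out-dir outputs --skip-psa
```

or in Python:

```python
from asuc_cua.runner import run_all
manifest = run_all(None, "outputs", seed=1, skip_psa=True)  # None = shipped config
```

With the shipped configuration and seed 1 this writes, among other
artifacts, `outputs/results_table.csv`:

```
         scenario  cost_infliximab  qaly_infliximab  cost_ciclosporin  qaly_ciclosporin  delta_cost  delta_qaly    cost_effectiveness
decision_tree_2yr        14619.652            1.518          6672.469             1.552
      markov_18yr        31403.524            8.974         13791.470             9.090
        base_case        46023.176           10.492         20463.940            10.641  -25559.236       0.149 ciclosporin dominates
```

Reading: over 20 years the infliximab strategy costs £46,023 and yields
10.49 QALYs per patient; ciclosporin costs £20,464 and yields 10.64 QALYs.
Ciclosporin is both cheaper (ΔC = −£25,559) and more effective
(ΔQALY = +0.149), so it *dominates* and no ICER is reported.  The split
rows show how much of each total accrues in the two-year tree versus the
18-year extrapolation.  `outputs/` also contains the synthetic patient
table, per-arm survival-fit comparisons (AIC/BIC), Weibull fits as JSON,
transition-probability schedules, cohort traces, the 13-row scenario
table, and a manifest with seeds, versions and runtimes.  Dropping
`--skip-psa` adds the CE-plane draws and the CEAC (≈ 30 s for 10,000
draws); `--plots` writes PNG figures.

Other subcommands expose the stages individually: `simulate`,
`fit-survival`, `run-dt`, `run-markov`, `run-cea`, `run-scenarios`,
`run-psa`.  Everything is driven by one YAML config
(`src/asuc_cua/data/default_config.yaml`); pass `--config` to override.

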