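# Methods

## The decision problem

Adults hospitalised with steroid-resistant acute severe ulcerative colitis
(ASUC) receive one of two rescue therapies — infliximab (an anti-TNF
monoclonal antibody) or ciclosporin (a calcineurin inhibitor) — to avoid
emergency colectomy.  The package estimates the relative cost-utility of
the two drugs from the UK NHS perspective: discounted costs (GBP) and
quality-adjusted life years (QALYs) per strategy over a 20-year horizon,
the incremental comparison (ciclosporin minus infliximab), and the
uncertainty around it.

The model is the standard two-stage design for an acute condition with
long-term consequences: a short-term decision tree covering the two trial
years, chained to an annual-cycle Markov cohort model for the following
18 years.

## Decision tree (years 0–2)

Both arms share one topology over three periods (0–3, 4–12, 13–24 months).
After induction a patient either achieves remission or fails and undergoes
colectomy; remitters can lose response and undergo colectomy mid-period
(8 months in period 2, 18.5 months in period 3; the model description gives
no timing for period-1 failures, so the package times them mid-period at
1.5 months).  Every colectomy resolves into straight surgical remission, a
treated post-operative complication (surgical remission from the start of
the next period), or perioperative death.  The within-trial mortality is
attached to the surgery node because one trial arm reported no deaths and
no other anchor exists; dead pathways accrue nothing further.

This yields a fixed set of 10 root-to-leaf pathways (3 colectomy entry
points × 3 surgical resolutions + sustained remission).  Each pathway
accrues utility × duration and annual cost × duration piecewise over its
state segments, plus one-off costs (induction drug at t=0, surgery and
complication at the event time).  Accruals beyond 12 months carry one
annual discount factor 1/(1+r) — annual compounding, matching the cohort
model's convention; the model description does not specify continuous vs
annual compounding.

## Survival extrapolation

The colectomy risk beyond the trial is extrapolated from the censored
two-year time-to-colectomy data by a proportional-hazards Weibull
regression

    h(t|x) = λγt^{γ−1} e^{x'β},   S(t|x) = exp(−λ t^γ e^{x'β}),

with age-at-randomisation and weight as covariates, so hazard ratios are
exp(β).  Covariates are centred at their sample means, making λ the
baseline scale at the mean covariate profile; whether the original
analysis predicted at means or at zero is not recoverable from the
published material, so both profiles are supported (`covariate_profile:
means|zero`) with *means* as the default.

Estimation is by direct maximisation of the right-censored log-likelihood
Σδᵢ log h(tᵢ) − ΣH(tᵢ) (Nelder–Mead polish followed by BFGS on
log-transformed positive parameters), with standard errors from the
inverse observed information and the delta method.  The exponential model
without covariates uses its closed-form MLE λ̂ = events/Σt.  Exponential,
Gompertz (PH form) and log-logistic (AFT form — it has no PH
representation) alternatives are fitted for comparison by AIC/BIC only;
coefficients are never compared across families.  The Gompertz shape is
allowed to be negative, since a declining hazard has no positive-shape
Gompertz representation.

A fitted (γ, λ) is turned into an annual transition-probability schedule
via the survival-ratio construction tp(t) = 1 − S(t)/S(t−1)
= 1 − exp(−λe^{x'β}(t^γ − (t−1)^γ)), t = 1..18.  The extrapolation clock
restarts at Markov entry (cycle 1 uses tp(1)).  For γ < 1 the schedule is
strictly decreasing; the cumulative colectomy probability telescopes to
1 − S(18) exactly, which is asserted at 1e-10.  Published multi-year
probabilities (e.g. 3-year mortality) are converted to annual via the
constant-rate transform r = −ln(1−P)/T, p₁ = 1 − e^{−r}.

## Markov cohort model (years 3–20)

Five states: remission on medical therapy, surgery, post-surgical
complications, surgical remission, dead (absorbing).  The cohort entering
cycle 1 is the end-of-tree state distribution, so mass is conserved across
the seam.  Surgery is a within-cycle tunnel: colectomy resolves in its own
cycle (emergency-colectomy mortality first, then complications among
survivors), occupancy is attributed to the destination state, and one-off
surgery/complication payoffs apply to the inflow mass.  Complications
resolve to surgical remission in the following cycle
(`p_complication_resolution`, default 1).  Background mortality at the
'no colectomy' annual rate applies in medical remission and — because the
source distinguishes only 'no colectomy' and 'emergency colectomy'
rates — also in surgical remission (config-overridable).  Competing risks
within a cycle are sequenced death-first, which keeps every transition-
matrix row a probability vector for any valid inputs, including extreme
PSA draws; rows are asserted to sum to 1 within 1e-12 and are never
renormalised.

Cycle-t payoffs are discounted by (1+r)^−(t+1) (year offset 2), so
discounting is continuous across the tree/cohort seam: calendar year 1 is
undiscounted, year y carries (1+r)^−(y−1).  No half-cycle correction is
applied by default (the source model does not mention one); a config
switch enables it.

A vectorised individual-level microsimulation of the identical dynamics
serves as an internal oracle: the cohort engine must agree with a
100,000-patient rollout within 3 Monte-Carlo SEs on randomised valid
configurations.

## Incremental analysis

Arm totals are the plain sum of tree and cohort components.  (The source
publication's combined row differs slightly from the sum of its printed
components with no stated adjustment; that discrepancy is not imitated.)
The comparator (ciclosporin) dominates iff ΔC < 0 and ΔE > 0; an ICER
ΔC/ΔE is reported only in the NE/SW quadrants, and is *undefined* (never
±∞) under dominance or ΔE = 0.  Net monetary benefit is wtp·ΔE − ΔC at the
£20,000/QALY NICE threshold.

## Sensitivity analyses

Twelve one-way deterministic scenarios ship by default: infliximab price
reductions of 10/20/50/70/80% (rescaling exactly the two drug-cost
components — induction cost and ongoing annual drug cost — so arm cost is
exactly linear in unit price), ±10% utilities per arm, a fixed annual
colectomy probability (0.07 infliximab / 0.10 ciclosporin) replacing the
Weibull schedule, and a 10-year horizon with either TP mode.  Structural
invariants: utility scenarios leave both cost columns unchanged; price
scenarios leave all QALYs unchanged; the fixed-TP scenario changes both.

The PSA performs 10,000 Monte-Carlo draws.  Utilities, Weibull λ and γ,
and annual mortality probabilities are drawn from moment-matched Beta
distributions (α = mν, β = (1−m)ν, ν = m(1−m)/se² − 1); state costs from
moment-matched Gamma distributions (k = m²/se², θ = se²/m).  Using a Beta
for λ and γ follows the source analysis verbatim even though they are not
probabilities; this is feasible only for means in (0,1) — true of all the
published point estimates — and config validation fails fast (before any
draw) otherwise, suggesting the SE reduction needed.  Parameters are drawn
independently; the decision-tree branch probabilities are not redrawn
(the published PSA scope names Markov-stage parameters plus utilities and
costs, which the tree shares).  The CEAC reports, per threshold, the
fraction of draws with positive net benefit; ties count as not
cost-effective (conservative, measure-zero).  The default WTP grid is
£0–£50,000 in £500 steps.  A 10,000-draw PSA takes well under a minute on
one CPU.

## Synthetic data

Patient-level trial data are access-restricted, so the package ships a
generator emulating the published cohort structure: 135 patients per arm,
ages 39.3 (SD 15.5) / 39.8 (15.0), two-year administrative censoring, and
event times drawn by inverting the PH-Weibull survival function at the
published regression estimates (γ, λ, hazard ratios per arm).  Ages are
truncated below at 18 (trial eligibility) and weights at 30 kg
(physiological floor); the truncated distribution's *mean* is calibrated
to the printed value, since printed cohort means describe the truncated
(adult) population.  Weight moments (75 ± 15 kg) and the independence of
age and weight are assumptions — the trial publishes neither — and are
flagged as such.

All state utilities, state costs, drug costs and mortality inputs in the
shipped configuration are likewise synthetic stand-ins for values held in
an unavailable appendix.  They respect the published qualitative
directions: ciclosporin utilities ≥ infliximab from 6 months on,
infliximab far costlier (induction ≈ £6,000 vs £1,200; ongoing drug cost
while in remission ≈ £2,600/yr vs £300/yr, since ciclosporin is usually
stopped by 12 weeks), ciclosporin with more colectomies, and 'no
colectomy' 3-year mortality (0.030) slightly above 'emergency colectomy'
(0.025).  Consequently the pipeline reproduces the *qualitative* published
findings (ciclosporin dominant in the base case and the fixed-TP scenario;
a high probability of cost-effectiveness at £20,000/QALY) but not the
published arm totals, which depend on the restricted inputs.  Passing
tests demonstrate the correctness of the machinery and the direction of
the economics, not the published point estimates.

## Numerical choices and problem sizes

- Reproducibility: one integer seed; `run_all` derives independent
  substreams for the generator and the PSA via `SeedSequence.spawn`.
  Identical seeds give byte-identical outputs.
- Tolerances: probability conservation 1e-12; schedule/annuity closed
  forms 1e-10; likelihood-oracle agreement 1e-6 (quadrature-limited);
  Monte-Carlo comparisons 3 SEs.
- Parameter-recovery checks simulate n = 20,000 per arm (≈ seconds per
  fit); the microsimulation oracle uses 100,000 patients; the
  decision-tree Monte-Carlo oracle uses 200,000 pathway rollouts.
- Degenerate inputs: zero-event data raise a fit error; probability 1
  cannot be converted to a rate; empty cohorts return empty tables;
  horizon must exceed the two tree years.

## Known limitations

- The synthetic payoffs make absolute cost/QALY totals illustrative only.
- No age-dependent background mortality (life tables), no elective
  colectomy pathway, no re-treatment or dose-escalation, no interval
  censoring or cure models, no correlation between PSA draws (a
  multivariate option for the Weibull parameters was considered and left
  out: the published analysis specifies independent per-parameter
  distributions).
- The decision tree holds utilities constant within states; no
  EQ-5D-3L item simulation.
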