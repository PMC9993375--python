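# Base-case configuration for the infliximab-vs-ciclosporin cost-utility model.
#
# The event-model parameters (Weibull shape/scale, covariate hazard ratios)
# and the cohort demographics reproduce the published trial-level summary
# statistics.  All state utilities, state costs, drug costs and mortality
# inputs are SYNTHETIC stand-ins chosen to respect the published qualitative
# structure (ciclosporin utilities >= infliximab; infliximab drug costs much
# higher; 'no colectomy' mortality slightly above 'emergency colectomy'):
# the originals live in a restricted trial dataset and are not public.

synthetic:
  seed: 20123
  censor_time_years: 2.0
  arms:
    infliximab:
      n: 135
      age_mean: 39.3
      age_sd: 15.5
      weight_mean: 75.0   # synthetic: trial does not publish weight moments
      weight_sd: 15.0
      event_model:
        shape: 0.393      # published Weibull gamma
        scale: 0.111      # published Weibull lambda (per year^gamma)
        beta_age: 0.008960   # ln(1.009), published age hazard ratio
        beta_weight: -0.011061  # ln(0.989)
    ciclosporin:
      n: 135
      age_mean: 39.8
      age_sd: 15.0
      weight_mean: 75.0
      weight_sd: 15.0
      event_model:
        shape: 0.450
        scale: 0.186
        beta_age: 0.021761   # ln(1.022)
        beta_weight: -0.024293  # ln(0.976)

survival:
  families: [weibull, exponential, gompertz, loglogistic]
  covariates: [age_at_randomisation, weight]
  covariate_profile: means   # transition schedules at the covariate means

decision_tree:           # branch probabilities are synthetic
  infliximab:
    p_initial_remission: 0.85
    p_colectomy_mid: 0.06
    p_colectomy_late: 0.05
    p_postop_complication: 0.30
    p_death_surgery: 0.02
    drug_cost_initial: 6000.0   # GBP, induction course (synthetic)
  ciclosporin:
    p_initial_remission: 0.82
    p_colectomy_mid: 0.09
    p_colectomy_late: 0.07
    p_postop_complication: 0.30
    p_death_surgery: 0.0
    drug_cost_initial: 1200.0

payoffs:                 # synthetic utilities (EQ-5D-3L scale) and GBP/year costs
  infliximab:
    utilities:
      remission_med: 0.78
      surgical_remission: 0.76
      complications: 0.60
      dead: 0.0
    annual_costs:
      remission_med: 1200.0
      surgical_remission: 500.0
      complications: 3000.0
      dead: 0.0
    one_off_costs:
      surgery: 9000.0
      complication: 2000.0
    annual_drug_cost_remission: 2600.0  # ongoing infliximab while in remission
  ciclosporin:
    utilities:
      remission_med: 0.80
      surgical_remission: 0.76
      complications: 0.60
      dead: 0.0
    annual_costs:
      remission_med: 1200.0
      surgical_remission: 500.0
      complications: 3000.0
      dead: 0.0
    one_off_costs:
      surgery: 9000.0
      complication: 2000.0
    annual_drug_cost_remission: 300.0   # ciclosporin usually stopped by 12 weeks

markov:
  p_complication_given_surgery: 0.30
  p_complication_resolution: 1.0   # complications resolve in the following cycle
  half_cycle_correction: false
  fixed_tp:                        # published fixed-TP scenario values
    infliximab: 0.07
    ciclosporin: 0.10
  mortality:                       # synthetic 3-year probabilities by pathway
    no_colectomy: 0.030
    emergency_colectomy: 0.025
    period_years: 3.0

economics:
  discount_rate: 0.035
  wtp: 20000.0
  horizon_years: 20
  price_year: 2019
  inflation_multiplier: 1.0

scenarios: default   # the twelve shipped one-way scenarios

psa:
  n_draws: 10000
  seed: 97531
  utility_se: 0.05
  cost_se_fraction: 0.2
  mortality_se: 0.005
  weibull:
    infliximab: {shape_se: 0.047, scale_se: 0.030}
    ciclosporin: {shape_se: 0.047, scale_se: 0.050}
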