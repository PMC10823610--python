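# Base-case parameter set for the edaravone dexborneol (EDB) vs human urinary
# kallidinogenase (HUK) acute-ischemic-stroke cost-effectiveness model.
# All monetary values in 2021 Chinese Yuan (CNY); probabilities as fractions.

arms:
  edb:
    # MAIC-adjusted day-90 mRS distribution (mRS 0..6)
    d90: [0.202, 0.406, 0.120, 0.193, 0.048, 0.031, 0.000]
    drug_price_per_unit: 33.0
    units_per_day: 6.0
    treatment_days: 14
  huk:
    d90: [0.190, 0.375, 0.178, 0.160, 0.083, 0.013, 0.001]
    drug_price_per_unit: 100.0
    units_per_day: 1.0
    treatment_days: 21

# Baseline mRS split (mRS 0 / mRS 1) of the enrolled cohort at randomization.
initial_mrs01_split: [0.903, 0.097]

costs:
  hospitalization:        # one-time, per stroke event, by mRS group
    mrs0_2: 12614.0
    mrs3_5: 17223.0
    mrs6: 13951.0
  annual_post_stroke:     # secondary-prevention cost, charged in stroke years
    mrs0_2: 9264.0
    mrs3_5: 14238.0
  hospital_days: 9.9      # recorded input; no formula in the model consumes it

utilities:
  mrs: [0.95, 0.89, 0.67, 0.44, 0.16, 0.10]   # mRS 0..5 annual QALY weights
  stroke_disutility: 0.086                     # charged in the year of a stroke

mortality:
  # China life table, annual all-cause mortality probability by age band
  life_table:
    - {age_lo: 60, age_hi: 64, q: 0.0075}
    - {age_lo: 65, age_hi: 69, q: 0.0117}
    - {age_lo: 70, age_hi: 74, q: 0.0203}
    - {age_lo: 75, age_hi: 79, q: 0.0356}
    - {age_lo: 80, age_hi: 84, q: 0.0629}
    - {age_lo: 85, age_hi: 89, q: 0.1028}
    - {age_lo: 90, age_hi: null, q: 0.1617}
  # mortality hazard ratio vs the general population, mRS 0..5
  hazard_ratios: [1.53, 1.52, 2.17, 3.18, 4.55, 6.55]

recurrence:
  # annual probability of recurrent ischemic stroke by years since index stroke
  annual_prob: [0.059, 0.036, 0.025, 0.022, 0.022, 0.027, 0.027, 0.023, 0.028]
  annual_prob_late: 0.016     # year 10 and beyond
  # redistribution[post][pre]: destination mRS given recurrence and survival;
  # each column sums to 0.8217, remainder 0.1783 is recurrence case fatality
  redistribution:
    - [0.1782, 0.0,    0.0,    0.0,    0.0,    0.0]
    - [0.2277, 0.4059, 0.0,    0.0,    0.0,    0.0]
    - [0.0891, 0.0891, 0.4950, 0.0,    0.0,    0.0]
    - [0.1188, 0.1188, 0.1188, 0.6138, 0.0,    0.0]
    - [0.1386, 0.1386, 0.1386, 0.1386, 0.7524, 0.0]
    - [0.0693, 0.0693, 0.0693, 0.0693, 0.0693, 0.8217]

economics:
  discount_rate_cost: 0.05
  discount_rate_outcome: 0.05
  wtp: 80976.0            # one-times 2021 GDP per capita, CNY per QALY
  horizon_cycles: 40
  cycle_length: 1.0
  start_age: 60

# Second-order (parameter-uncertainty) sampling distributions.
# gamma: shape alpha, scale beta (mean = alpha*beta)
# beta: shape alpha, shape beta (mean = alpha/(alpha+beta))
# lognormal: log-mean alpha, log-sd beta (median = exp(alpha))
psa:
  hosp_cost_mrs0_2:  {family: gamma, alpha: 17494.59, beta: 0.72}
  hosp_cost_mrs3_5:  {family: gamma, alpha: 7860.91, beta: 2.19}
  hosp_cost_mrs6:    {family: gamma, alpha: 548.15, beta: 25.45}
  post_cost_mrs0_2:  {family: gamma, alpha: 3909.41, beta: 2.37}
  post_cost_mrs3_5:  {family: gamma, alpha: 1235.08, beta: 11.53}
  utility_mrs0:      {family: beta, alpha: 56315.05, beta: 2963.95}
  utility_mrs1:      {family: beta, alpha: 10469.23, beta: 1293.95}
  utility_mrs2:      {family: beta, alpha: 803.62, beta: 395.81}
  utility_mrs3:      {family: beta, alpha: 172.72, beta: 219.83}
  utility_mrs4:      {family: beta, alpha: 126.72, beta: 665.28}
  utility_mrs5:      {family: beta, alpha: 7.68, beta: 69.10}
  stroke_disutility: {family: beta, alpha: 38.33, beta: 407.36}
  hr_mrs0:           {family: lognormal, alpha: 0.43, beta: 0.10}
  hr_mrs1:           {family: lognormal, alpha: 0.42, beta: 0.11}
  hr_mrs2:           {family: lognormal, alpha: 0.77, beta: 0.01}
  hr_mrs3:           {family: lognormal, alpha: 1.16, beta: 0.002}
  hr_mrs4:           {family: lognormal, alpha: 1.52, beta: 0.03}
  hr_mrs5:           {family: lognormal, alpha: 1.88, beta: 0.03}

# One-way deterministic sensitivity ranges
dsa:
  - {param: drug_price_edb, low: 33.0, high: 49.0}
  - {param: drug_price_huk, low: 90.0, high: 100.0}
  - {param: hosp_cost_mrs0_2, low: 12428.0, high: 12802.0}
  - {param: hosp_cost_mrs3_5, low: 16845.0, high: 17606.0}
  - {param: hosp_cost_mrs6, low: 12819.0, high: 15155.0}
  - {param: post_cost_mrs0_2, low: 8977.0, high: 9558.0}
  - {param: post_cost_mrs3_5, low: 13460.0, high: 15049.0}
  - {param: utility_mrs0, low: 0.90, high: 1.00}
  - {param: utility_mrs1, low: 0.78, high: 1.00}
  - {param: utility_mrs2, low: 0.48, high: 0.86}
  - {param: utility_mrs3, low: 0.20, high: 0.68}
  - {param: utility_mrs4, low: 0.00, high: 0.35}
  - {param: utility_mrs5, low: 0.00, high: 0.28}
  - {param: stroke_disutility, low: 0.060, high: 0.112}
  - {param: hr_mrs0, low: 1.23, high: 1.83}
  - {param: hr_mrs1, low: 1.20, high: 1.83}
  - {param: hr_mrs2, low: 2.14, high: 2.20}
  - {param: hr_mrs3, low: 3.17, high: 3.19}
  - {param: hr_mrs4, low: 4.31, high: 4.78}
  - {param: hr_mrs5, low: 6.12, high: 6.98}
  - {param: discount_rate_cost, low: 0.00, high: 0.08}
  - {param: discount_rate_outcome, low: 0.00, high: 0.08}
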