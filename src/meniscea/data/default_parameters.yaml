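# Base-case parameters for the meniscal tear + knee OA treatment model.
# Probabilities for pain transitions during the treatment window are quarterly;
# natural-history rates (KL progression, OA incidence, TKA uptake, OA pain,
# pharmacologic adverse events) are annual.  Costs in 2013 USD.
cohort:
  mean_age: 58
  sd_age: 7
  age_range: [45, 75]
  kl_shares: {kl01: 0.448, kl2: 0.264, kl3: 0.288, kl4: 0.0}

kl_progression:
  kl2_to_kl3: 0.0735
  kl3_to_kl4: 0.0267

oa_incidence_by_age:
  - {ages: [45, 54], annual: 0.00379}
  - {ages: [55, 64], annual: 0.00668}
  - {ages: [65, 74], annual: 0.00375}
  - {ages: [75, 84], annual: 0.00306}
  - {ages: [85, 200], annual: 0.00310}

tka_uptake_by_age:
  - {ages: [45, 64], annual: 0.064}
  - {ages: [65, 84], annual: 0.119}
  - {ages: [85, 200], annual: 0.030}

utilities: {low: 0.869, moderate: 0.771, dead: 0.0}

# Quarterly pain transition probabilities attributable to the index treatment,
# by treatment context and KL band.  failed_relief applies months 0-3;
# incidence/resolution months 3-6.  The crossover context (APM_after_PT) has a
# single failed-relief window in the quarter after surgery.
treatment_pain:
  APM:
    failed_relief: {KL02: {beta: [29, 61]}, KL34: {beta: [21, 22]}}
    incidence:     {KL02: {beta: [14, 47]}, KL34: {beta: [8, 14]}}
    resolution:    {KL02: {beta: [14, 15]}, KL34: {beta: [7, 14]}}
  APM_after_PT:
    failed_relief: {KL02: {beta: [6, 9]},   KL34: {beta: [6, 3]}}
    incidence:     {KL02: {fixed: 0.0},     KL34: {fixed: 0.0}}
    resolution:    {KL02: {fixed: 0.0},     KL34: {fixed: 0.0}}
  PT:
    failed_relief: {KL02: {beta: [58, 44]}, KL34: {beta: [26, 11]}}
    incidence:     {KL02: {beta: [10, 34]}, KL34: {beta: [2, 9]}}
    resolution:    {KL02: {beta: [9, 49]},  KL34: {beta: [3, 23]}}

# Annual OA-driven pain dynamics, by KL grade (applies after month 6).
oa_pain:
  incidence:  {KL01: 0.075, KL2: 0.085, KL3: 0.212, KL4: 0.190}
  resolution: {KL01: 0.085, KL2: 0.037, KL3: 0.040, KL4: 0.005}

# Annual probability of low pain after knee replacement.
tka_efficacy: {first_year: 0.862, subsequent: 0.960}

adverse_events:
  APM:   {prob: 0.015, mortality: 0.011}
  TKA:   {prob: 0.036, mortality: 0.006}
  pharm: {prob_annual: 0.111, mortality: 0.005}

costs:
  apm_procedure: {fixed: 2867}
  apm_complication: {fixed: 11589}
  apm_post_healthcare: {gamma: [703, 1.5], mean: 454}
  apm_rehab: {gamma: [351, 0.8], mean: 439}
  pt_healthcare: {gamma: [117, 0.6], mean: 209}
  pt_rehab: {gamma: [352, 0.6], mean: 568}
  pain_mgmt_moderate: {gamma: [129, 0.5], mean: 276}
  pain_mgmt_low: {gamma: [160, 1.6], mean: 99}
  pain_mgmt_complication: {fixed: 1816}
  tka_procedure: {fixed: 20282}
  tka_complication: {fixed: 15149}

time_costs:
  wage_rate: 22.33
  hours:
    apm_q1: {gamma: [79, 0.7], mean: 109}
    pt_q1: {gamma: [22, 0.3], mean: 79}
    q2_moderate: {gamma: [32, 0.4], mean: 87}
    q2_low: {gamma: [68, 1.6], mean: 42}
    later_moderate: {gamma: [94, 1.4], mean: 70}
    later_low: {gamma: [89, 3.0], mean: 30}

# Probability of employment by age.  The trial population was ~60% employed;
# hours lost in the first six months are already averaged over employed and
# unemployed subjects, so the schedule weights only the long-run (after month
# 6) productivity losses.  Linear interpolation between breakpoints.
employment:
  schedule: [[45, 0.60], [110, 0.60]]

discount_rate_annual: 0.03
horizon_years: 10
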