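# Default model inputs for the social-anxiety-disorder cost-utility model.
# Every field can be overridden through the run configuration; the values
# mirror the in-code defaults of sadcea.parameters.ModelParameters.
#
# Categorical distributions are written as probability groups; when a group
# names several values its probability mass is split equally among them.

treatment_weeks: 12
horizon_years_post_treatment: 5
discount_rate: 0.035
wtp_threshold: 20000.0

utility_recovered: 0.866
utility_sad: 0.659
utility_recovered_dist: {family: beta-counts, alpha: 4572, beta: 707}
utility_sad_dist: {family: beta-counts, alpha: 40, beta: 20}

annual_cost_recovered: 645.0
annual_cost_sad: 1037.0
cost_recovered_dist: {family: gamma-mean-se, mean: 645.0, se: 93.0}
cost_sad_dist: {family: gamma-mean-se, mean: 1037.0, se: 209.0}

# Year-1 relapse after recovery on a drug: midpoint of the pooled relapse
# risk during maintenance treatment and the pooled risk after switch to
# placebo (five relapse-prevention trials).
relapse_drug_y1_dist:
  {family: midpoint-of-two-betas, alpha1: 107, beta1: 293, alpha2: 222, beta2: 170}

# Risk ratio of year-1 relapse, drugs vs psychological therapy.
relapse_rr_point: 3.0
relapse_rr_dist: {family: log-normal-ci, mean: 3.0, ci_low: 0.73, ci_high: 12.39}

# Twelve-year recovery / recurrence probabilities from the naturalistic
# long-term follow-up study; converted to annual probabilities assuming a
# constant hazard.
recovery_y2_5_12yr_dist: {family: beta-counts, alpha: 65, beta: 111}
relapse_y2_5_12yr_dist: {family: beta-counts, alpha: 26, beta: 40}

# Year-1 relapse on wait list is not reported; default is the annualised
# years-2-5 relapse probability (same source, constant hazard). Set to null
# to keep that default or supply a probability.
relapse_waitlist_y1: null

gp_visit_unit_cost: 46.75
gp_visits_initial_dist:
  family: categorical-groups
  groups:
    - {prob: 0.65, values: [4]}
    - {prob: 0.10, values: [3, 5, 6]}
    - {prob: 0.25, values: [1, 2]}
gp_visits_maintenance_dist:
  family: categorical-groups
  groups:
    - {prob: 0.55, values: [3]}
    - {prob: 0.45, values: [0, 1, 2, 4]}

# Shared wait-list baseline: log-odds of recovery at end of treatment.
baseline_log_odds_mean: -2.629
baseline_log_odds_variance: 1.235
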