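# Default cohort-simulation parameters, version 1.
# Marginals follow the published characteristics of a large US registry
# breast-cancer cohort (2000-2020 diagnoses); node-count supports are
# 1-5 removed nodes for SLNB and 4-82 for ALND.
version: 1
n: 1000
seed: 0

age_probs: {"<50": 0.203, "50-74": 0.633, ">=75": 0.164}
year_mean: 2010.18
year_sd: 6.014
year_range: [2000, 2020]
t_probs: {0: 0.001, 1: 0.697, 2: 0.302}
n_probs: {0: 0.731, 1: 0.205, 2: 0.046, 3: 0.018}
histology_probs: {ductal: 0.753, lobular: 0.087, mixed: 0.100, other: 0.060}
grade_probs: {1: 0.251, 2: 0.453, 3: 0.296}
p_er: 0.844
p_pr: 0.739
p_her2: 0.130
p_bcs: 0.598
p_systemic: 0.698
p_radiotherapy: 0.526
tx_delay_mean: 1.002
tx_delay_sd: 1.029

# Latent-procedure assignment: logistic model for P(ALND) among N0/N1
# subjects; N2/N3 subjects always receive ALND.
assignment:
  intercept: -1.58
  year_c: -0.13
  n1: 2.00
  t2: 0.55
  grade3: 0.35
  age_lt50: 0.25
  her2: 0.25

# Removed-node counts: discretised truncated normals per procedure.
slnb_nodes: {mean: 2.368, sd: 1.252, low: 1, high: 5}
alnd_nodes: {mean: 13.382, sd: 6.435, low: 4, high: 82}
# Geometric decay of positive-node counts within the pN bin.
positive_decay: 0.55

# Cause-specific survival mechanism: exponential event times with
# hazard = baseline_hazard * exp(linear predictor).
baseline_hazard: 0.0006
log_hazard:
  alnd: 0.0
  age_lt50: 0.10
  age_ge75: 0.50
  year_c: -0.01
  t2: 0.50
  grade2: 0.30
  grade3: 0.70
  er: -0.60
  pr: -0.30
  her2: 0.10
  bcs: -0.10
  systemic: -0.20
  radiotherapy: -0.10
  tx_delay: 0.02
  n1: 0.50
  n2: 0.90
  n3: 1.20
  nodes_positive: 0.10
  nodes_removed: 0.0
  node_ratio: 0.0
horizon_months: 252.0
study_end_year: 2022
censoring_rate: 0.002
round_months: false

# Rates at which selection-test flags are switched on (all zero by
# default: a clean analysis-ready cohort).
exclusion_rates:
  tis: 0.0
  m1: 0.0
  t3t4: 0.0
  nonepithelial: 0.0
  neoadjuvant: 0.0
  no_surgery: 0.0
  missing_core: 0.0

# Per-field missingness: {field: {rate: r, mechanism: MCAR|MAR}}.
missingness: {}
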