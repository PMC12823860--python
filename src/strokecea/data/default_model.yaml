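# Default model specification: cost-utility of extended-window intravenous
# alteplase versus standard medical therapy for posterior circulation
# ischemic stroke, Chinese healthcare-system perspective, 2024 CNY.
#
# provenance: PAPER   = printed in the source trial/cost/utility literature
#             ASSUMED = packaged default standing in for an unprinted
#                       literature value; override freely.
schema: strokecea-model/1
config:
  start_age: 64.0
  horizon_years: 30.0
  cycle_length_years: 0.25
  half_cycle_correction: true
  rng_seed: 20240
  psa_iterations: 1000
discount:
  annual_rate: {value: 0.05, range: [0.0, 0.08], dist: fixed, provenance: PAPER}
thresholds:
  gdp_per_capita: 95749.0
comparator:
  name: standard
  includes_drug_cost: false
  mrs_at_3mo:
    values: [0.2564, 0.3504, 0.1197, 0.1197, 0.0342, 0.0342, 0.0855]
    ranges:
      - [0.1773, 0.3355]
      - [0.2640, 0.4369]
      - [0.0609, 0.1785]
      - [0.0609, 0.1785]
      - [0.0013, 0.0671]
      - [0.0013, 0.0671]
      - [0.0348, 0.1361]
    dist: dirichlet
    concentration: 115.0
    provenance: PAPER
  sich_incidence: {value: 0.0087, range: [0.0, 0.0409], dist: beta, provenance: PAPER}
intervention:
  name: alteplase
  includes_drug_cost: true
  mrs_at_3mo:
    values: [0.3913, 0.3478, 0.1565, 0.0261, 0.0174, 0.0087, 0.0522]
    ranges:
      - [0.3021, 0.4805]
      - [0.2608, 0.4349]
      - [0.0901, 0.2229]
      - [0.0, 0.0552]
      - [0.0, 0.0413]
      - [0.0, 0.0257]
      - [0.0115, 0.0928]
    dist: dirichlet
    concentration: 115.0
    provenance: PAPER
  sich_incidence: {value: 0.0172, range: [0.0, 0.0257], dist: beta, provenance: PAPER}
utilities:
  u_mrs:
    values: [0.95, 0.89, 0.67, 0.44, 0.16, 0.10, 0.0]
    ranges:
      - [0.855, 1.0]
      - [0.801, 0.979]
      - [0.603, 0.737]
      - [0.396, 0.484]
      - [0.144, 0.176]
      - [0.09, 0.11]
      - [0.0, 0.0]
    dist: beta
    provenance: PAPER
    range_provenance: ASSUMED
  u_recurrence: {value: 0.42, range: [0.336, 0.504], dist: beta, provenance: PAPER, range_provenance: ASSUMED}
  d_sich: {value: 0.38, range: [0.304, 0.456], dist: beta, provenance: PAPER, range_provenance: ASSUMED}
costs:
  acute_hosp_by_mrs:
    values: [15000.0, 18000.0, 25000.0, 35000.0, 45000.0, 55000.0, 20000.0]
    ranges:
      - [11250.0, 18750.0]
      - [13500.0, 22500.0]
      - [18750.0, 31250.0]
      - [26250.0, 43750.0]
      - [33750.0, 56250.0]
      - [41250.0, 68750.0]
      - [15000.0, 25000.0]
    dist: gamma
    provenance: ASSUMED
  annual_care_mrs01: {value: 8000.0, range: [6000.0, 10000.0], dist: gamma, provenance: ASSUMED}
  annual_care_mrs25: {value: 40000.0, range: [30000.0, 50000.0], dist: gamma, provenance: ASSUMED}
  recurrent_stroke_event: {value: 30000.0, range: [22500.0, 37500.0], dist: gamma, provenance: ASSUMED}
  sich_event: {value: 20000.0, range: [15000.0, 25000.0], dist: gamma, provenance: ASSUMED}
  alteplase_price_20mg: 1700.0
  alteplase_price_50mg: 3400.0
  alteplase_base_case: {value: 2550.0, range: [1700.0, 3400.0], dist: gamma, provenance: PAPER}
life_table:
  # 5-year bands, lower age bound -> annual all-cause mortality probability
  bands:
    - [60.0, 0.00760]
    - [65.0, 0.01266]
    - [70.0, 0.02159]
    - [75.0, 0.03731]
    - [80.0, 0.06340]
    - [85.0, 0.15120]
  provenance: PAPER
mortality:
  hr_by_mrs:
    values: [1.0, 1.0, 1.11, 1.27, 1.71, 2.37]
    ranges:
      - [1.0, 1.2]
      - [1.0, 1.2]
      - [0.89, 1.3]
      - [1.02, 1.52]
      - [1.37, 2.05]
      - [1.90, 2.84]
    dist: fixed
    provenance: PAPER
  post_stroke_excess_hr: {value: 1.0, range: [1.0, 1.2], dist: fixed, provenance: ASSUMED}
recurrence:
  annual_recurrence_by_mrs:
    values: [0.02, 0.02, 0.04, 0.04, 0.06, 0.06]
    ranges:
      - [0.01, 0.03]
      - [0.01, 0.03]
      - [0.02, 0.06]
      - [0.02, 0.06]
      - [0.03, 0.09]
      - [0.03, 0.09]
    dist: beta
    provenance: ASSUMED
  case_fatality: {value: 0.21, range: [0.158, 0.263], dist: beta, provenance: PAPER, range_provenance: ASSUMED}
  p_stay_given_survive: {value: 0.5, range: [0.25, 0.75], dist: fixed, provenance: ASSUMED}
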