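name: atacc_model_b
form: cox_baseline_survival
horizon: 10.0
outcome: all_cvd
version: '1.0'
source: Cox calculators developed on a pooled 13-center RA cohort; coefficients per
  decade of age, baseline survival at the reference profile (age 55.3, female, non-smoker,
  normotensive, TC:HDL 2.17, DAS28ESR 4.0, HAQ 0.73).
unit_system: mmol/L
blocks_by: stratum
age_range:
- 18
- 100
blocks:
  high:
    baseline_survival: 0.916
    lp_reference: 3.7468999999999997
    terms: &id001
    - coef: 0.473
      expr: age10
    - coef: 0.476
      expr: male
    - coef: 0.419
      expr: current_smoker
    - coef: 0.64
      expr: hypertension
    - coef: 0.416
      expr: tc_hdl_ratio
    - coef: 0.313
      expr: haq
  low:
    baseline_survival: 0.968
    lp_reference: 3.7468999999999997
    terms: *id001
reference:
  age10: 5.53
  male: 0.0
  current_smoker: 0.0
  hypertension: 0.0
  tc_hdl_ratio: 2.17
  das28esr: 4.0
  haq: 0.73
test_vectors:
- subject: &id002
    age: 55.3
    sex: female
    smoking: never
    hypertension: 0
    tc: 2.821
    hdl: 1.3
    das28esr: 4.0
    haq: 0.73
  stratum: high
  risk: 0.084
  tol: 1.0e-06
- subject: *id002
  stratum: low
  risk: 0.032
  tol: 1.0e-06
checksum: 9efe78579a31e321e539f2efc64c8083b2b36df1af77454c8811afdf116dc4f6
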