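name: atacc_model_a
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
    baseline_survival: 0.921
    lp_reference: 3.90726
    terms: &id001
    - coef: 0.482
      expr: age10
    - coef: 0.479
      expr: male
    - coef: 0.416
      expr: current_smoker
    - coef: 0.531
      expr: hypertension
    - coef: 0.34
      expr: tc_hdl_ratio
    - coef: 0.126
      expr: das28esr
  low:
    baseline_survival: 0.963
    lp_reference: 3.90726
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
  risk: 0.079
  tol: 1.0e-06
- subject: *id002
  stratum: low
  risk: 0.037
  tol: 1.0e-06
checksum: c27b192d4fa2a81b483477acfe4e4d0478110f44bec0f73a455fb03ac1fd2bd7
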