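name: acc_aha_pce
form: cox_baseline_survival
horizon: 10.0
outcome: hard_ascvd
version: '1.0'
source: Pooled Cohort Equations, 2013 ACC/AHA guideline on the assessment of cardiovascular
  risk; white/other coefficient sets (the pooled RA cohorts are almost exclusively
  Caucasian).
unit_system: mmol/L
blocks_by: sex
age_range:
- 40
- 79
blocks:
  female:
    baseline_survival: 0.9665
    lp_reference: -29.18
    terms:
    - coef: -29.799
      expr: log(age)
    - coef: 4.884
      expr: log(age)**2
    - coef: 13.54
      expr: log(tc_mgdl)
    - coef: -3.114
      expr: log(age)*log(tc_mgdl)
    - coef: -13.578
      expr: log(hdl_mgdl)
    - coef: 3.149
      expr: log(age)*log(hdl_mgdl)
    - coef: 2.019
      expr: log(sbp)*antihypertensive_use
    - coef: 1.957
      expr: log(sbp)*(1-antihypertensive_use)
    - coef: 7.574
      expr: current_smoker
    - coef: -1.665
      expr: log(age)*current_smoker
    - coef: 0.661
      expr: diabetes
  male:
    baseline_survival: 0.9144
    lp_reference: 61.18
    terms:
    - coef: 12.344
      expr: log(age)
    - coef: 11.853
      expr: log(tc_mgdl)
    - coef: -2.664
      expr: log(age)*log(tc_mgdl)
    - coef: -7.99
      expr: log(hdl_mgdl)
    - coef: 1.769
      expr: log(age)*log(hdl_mgdl)
    - coef: 1.797
      expr: log(sbp)*antihypertensive_use
    - coef: 1.764
      expr: log(sbp)*(1-antihypertensive_use)
    - coef: 7.837
      expr: current_smoker
    - coef: -1.795
      expr: log(age)*current_smoker
    - coef: 0.658
      expr: diabetes
test_vectors:
- subject:
    age: 55
    sex: female
    tc: 5.508145849495733
    hdl: 1.2929919834497026
    sbp: 120
    antihypertensive_use: 0
    smoking: never
    diabetes: 0
  risk: 0.021
  tol: 0.002
- subject:
    age: 55
    sex: male
    tc: 5.508145849495733
    hdl: 1.2929919834497026
    sbp: 120
    antihypertensive_use: 0
    smoking: never
    diabetes: 0
  risk: 0.053
  tol: 0.003
checksum: 60ab8ef5d1865e45ef65d44795f9f56cb71542b24bf6fe1091de7239b197817c
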