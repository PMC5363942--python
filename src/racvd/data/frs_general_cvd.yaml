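name: frs_general_cvd
form: cox_baseline_survival
horizon: 10.0
outcome: general_cvd
version: '1.0'
source: General cardiovascular disease risk profile, Framingham Heart Study (D'Agostino
  et al., Circulation 2008); sex-specific Cox equations on log-transformed risk factors.
unit_system: mmol/L
blocks_by: sex
age_range:
- 30
- 74
blocks:
  female:
    baseline_survival: 0.95012
    lp_reference: 26.1931
    terms:
    - coef: 2.32888
      expr: log(age)
    - coef: 1.20904
      expr: log(tc_mgdl)
    - coef: -0.70833
      expr: log(hdl_mgdl)
    - coef: 2.76157
      expr: log(sbp)*(1-antihypertensive_use)
    - coef: 2.82263
      expr: log(sbp)*antihypertensive_use
    - coef: 0.52873
      expr: current_smoker
    - coef: 0.69154
      expr: diabetes
  male:
    baseline_survival: 0.88936
    lp_reference: 23.9802
    terms:
    - coef: 3.06117
      expr: log(age)
    - coef: 1.1237
      expr: log(tc_mgdl)
    - coef: -0.93263
      expr: log(hdl_mgdl)
    - coef: 1.93303
      expr: log(sbp)*(1-antihypertensive_use)
    - coef: 1.99881
      expr: log(sbp)*antihypertensive_use
    - coef: 0.65451
      expr: current_smoker
    - coef: 0.57367
      expr: diabetes
test_vectors:
- subject:
    age: 61
    sex: female
    tc: 4.654771140418929
    hdl: 1.2154124644427204
    sbp: 124
    antihypertensive_use: 0
    smoking: current
    diabetes: 0
  risk: 0.1048
  tol: 0.002
checksum: bd84e2daa1272dd830637671f0bdf59253273ee89e3208ee065245f10a93f959
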