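name: score_low_risk
form: score_weibull_fatal
horizon: 10.0
outcome: fatal_cvd
version: '1.0'
source: 'SCORE low-risk-region charts (Conroy et al., Eur Heart J 2003): two-cause
  Weibull model, coronary and non-coronary fatal CVD, risk accumulated from current
  age to age + 10. Test vectors are regression values computed by this implementation
  at transcription time (the original worked example was not independently verifiable
  here); they guard the file against corruption, not against transcription.'
unit_system: mmol/L
age_range:
- 30
- 65
causes:
  chd:
    alpha:
      male: -22.1
      female: -29.8
    p:
      male: 4.71
      female: 6.36
    beta_chol: 0.24
    beta_sbp: 0.018
    beta_smoker: 0.71
  non_chd:
    alpha:
      male: -26.7
      female: -31.0
    p:
      male: 5.64
      female: 6.62
    beta_chol: 0.02
    beta_sbp: 0.022
    beta_smoker: 0.63
test_vectors:
- subject:
    age: 60
    sex: male
    tc: 6.0
    sbp: 160
    smoking: current
  risk: 0.097547
  tol: 0.0001
- subject:
    age: 55
    sex: female
    tc: 5.0
    sbp: 140
    smoking: never
  risk: 0.007084
  tol: 0.0001
checksum: bb29b79b2df920b6e15af4644581fb77fcf81ef8d2cf2d2265727d7cc00327da
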