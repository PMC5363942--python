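# Methods

This note documents the statistical machinery in `racvd`: the models, the
synthetic-data generator and what it does and does not emulate, numerical
conventions, and known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The risk model

The calculators are stratified Cox proportional-hazards models,

h(t | x, s) = h0_s(t) · exp(β′(x − x_ref)),

with two center strata s ∈ {high, low} (centers grouped by their crude CVD
event rate, because a single pooled baseline cannot absorb a 20-fold spread
in rates) and coefficients shared across strata. Ten-year absolute risk is
1 − S0_s(10)^exp(β′(x − x_ref)) with S0_s = exp(−H0_s), H0_s the Breslow
cumulative-hazard estimator. The linear predictor is centered at a fixed
reference profile — age 55.3 y, female, non-smoker, no hypertension,
TC:HDL 2.17, DAS28ESR 4.0, HAQ 0.73 — so the published baseline survivals
(0.921/0.963 for the DAS28ESR calculator, 0.916/0.968 for the HAQ one) refer
to a subject at that profile. Both strata are centered at this single
profile. Note one internal oddity of the published numbers that we preserve
rather than repair: the reference TC:HDL of 2.17 is far below the cohort
mean ratio (≈ 5.2/1.5 ≈ 3.5); we honor the printed value for centering and
flag it here.

Covariate codings are explicit in the design-column names: `age10` is age in
decades (all age coefficients are per 10 years), `esr10`/`crp10`/`*_vas10`/
`ra_duration10` are per-10-unit codings, `log_*` natural-log codings.

### Estimation

- Partial-likelihood maximization uses lifelines (Efron ties, the less
  biased convention when ties exist; simulated times are continuous so the
  choice is mostly cosmetic). A Breslow-ties full-Newton fitter is built into
  the package (convergence: max |score| < 1e-8 or relative log-likelihood
  change < 1e-9) and doubles as a cross-check; the two agree to ≈1e-5 on
  tie-free data.
- Baseline survival is computed in-package by the Breslow estimator on the
  reference-centered linear predictor, because off-the-shelf baselines are
  centered at training means and would not reproduce the published scale.
  Queries beyond the last observed time carry the last value.
- Fits with fewer than two events return a flagged degenerate result (a
  single event gives a monotone partial likelihood).

### Variable selection

CVD risk-factor selection is L1-penalized stratified Cox over 19 candidates
(age, sex, current/ever smoking, SBP/DBP raw and log, TC, HDL, LDL,
triglycerides, TC:HDL, BMI, family history, diabetes, hypertension,
antihypertensive and lipid-lowering use). No installed Python package
supports strata in penalized Cox, so the engine is written here in the
glmnet style: outer IRLS on the Breslow partial likelihood (diagonal
information weights), inner cyclic coordinate descent with covariance
updates, warm starts along a 40-point geometric penalty path down to 2% of
the smallest penalty that zeroes all coefficients. Candidates are
standardized internally by within-dataset SD; coefficients are reported
unstandardized. At zero penalty the engine matches the unpenalized fit to
≈1e-6 (tested), and its cross-validated penalty at the deviance minimum
matches R's glmnet on identical data.

Cross-validation uses 10 folds stratified on (stratum × event status) and
the deviance-difference form D_k = −2(ℓ(β; all) − ℓ(β; train)), which is
stable in small folds; the selected penalty is the largest one with mean CV
deviance within one standard error of the minimum (1-SE rule). Across
imputed datasets the final set is the majority vote.

RA disease characteristics (RF, ACPA, RF/ACPA, ESR linear and log, CRP
linear and log, DAS28ESR, joint counts, patient and physician VAS, disease
duration, HAQ) are then assessed one at a time on top of the selected CVD
adjustors, each fitted only on the centers that measured it, because several
characteristics are absent from whole centers. The two final calculators add
DAS28ESR (Model A) or HAQ (Model B) to the base set. "No further
characteristic adds" is operationalized as a forward step with a pooled Wald
entry threshold of p < 0.05 (the threshold is our choice; only the outcome
is published).

### Diagnostics

Proportional hazards is checked by the scaled-Schoenfeld correlation test
(rank time transform); the reported global statistic is the sum of
per-covariate chi-squares (an approximation, documented as such).
Non-linearity is checked per continuous covariate by a likelihood-ratio test
of a linear term against a restricted cubic spline with 4 knots at the
5/35/65/95-percentiles (2 df).

## Multiple imputation

Chained equations via statsmodels' MICE with predictive mean matching
(donor pool 20), m = 10 completed datasets, 10 iterations per chain by
default, per-dataset seeds derived from one master seed. Lipids enter the
chains on the natural-log scale and are back-transformed, so imputed values
are strictly positive; TC:HDL is always recomputed from completed TC and
HDL, never imputed directly; the event indicator, follow-up time and cohort
indicators are predictors in every chain. Variables absent from an entire
center (block-missing) are re-masked after the chains run, so models using
them are fitted on measured centers only — imputing a whole center's HAQ
from other centers' joint distribution would manufacture information;
a flag exists for users who want it anyway.

Downstream estimates are pooled by Rubin's rules — pooled point estimate is
the mean, total variance W + (1 + 1/m)B — with the Barnard–Rubin
degrees-of-freedom adjustment when a complete-data df is supplied and the
large-sample df otherwise.

## Validation machinery

- **Discrimination**: Harrell's c for censored data — usable pairs are those
  orderable under censoring (the earlier subject had an event), prediction
  ties count 1/2. The CI is a Noether-type normal approximation on the
  concordance proportion with the usable-pair count as denominator; it
  ignores pair dependence and is therefore somewhat narrow (documented
  trade-off; the point estimate is exact and is tested against an O(n²)
  brute-force pair count to 1e-12).
- **Expected events** accumulate over each subject's own exposure:
  E_i = H_i(min(t_i, 10)). Fitted models supply H_i exactly from their
  Breslow baseline; for calculators that publish only a 10-year baseline
  survival, the cumulative hazard is scaled linearly in time (exact for a
  constant hazard, a stated convention otherwise). Only events within the
  horizon enter the observed count O.
- **SIR** = O/E with exact Poisson limits on O (chi-square quantile form).
- **Decile calibration**: subjects grouped by deciles of predicted risk;
  the reported observed risk per decile is Kaplan–Meier at the horizon
  (robust to censoring) while the chi-square compares observed event counts
  with expected events, Σ(O_g − E_g)²/E_g on g − 1 − penalty df: penalty 1
  when the model is evaluated in the data used to fit it, 0 externally.
  Groups with expected events below 1 are merged with a warning. Simulation
  (500 calibrated replicates at n = 5000, fitted-and-evaluated in-sample)
  puts the test's type-I error within the 3–7% band.
- **10-fold cross-validation** stratified on (stratum × event status); every
  subject is predicted exactly once out-of-fold; c, SIR and the decile test
  are computed on pooled out-of-fold predictions; the apparent
  (resubstitution) c is reported alongside for over-optimism checks.
- **Reclassification**: 4×4 cross-classification of two calculators over the
  categories <5%, 5–<10%, 10–<20%, ≥20% (left-closed bins), split by event
  status, with per-cell KM 10-year risk; summary percentages (same / higher
  / lower) are computed over all subjects and rounded to integers. One
  published inconsistency is documented rather than matched: the printed
  "46% remained in the same category" for the high-risk stratum disagrees
  with the printed counts themselves, whose diagonal is 1519/2697 ≈ 56%; the
  package asserts the computed 56 (the printed marginals 36% higher / 8%
  lower are reproduced exactly, as are all low-stratum percentages).
  The net reclassification index is deliberately not implemented: it is not
  recommended in the presence of miscalibration, which is exactly the
  regime this machinery is for.

## Comparator risk equations

Comparator calculators are data files, not code: versioned YAML with
coefficients, transform expressions, reference linear predictors, baseline
survival (or the two-cause Weibull parameters of the fatal-CVD SCORE form),
validity age ranges, a payload checksum, and worked-example test vectors
re-evaluated at every load, so a mistranscribed or corrupted file refuses to
load. Shipped files: the two RA calculators, the Framingham general-CVD
profile (sex-specific, log-transformed risk factors; its published worked
example — a 61-year-old woman, ≈10.5% — passes), the ACC/AHA pooled cohort
equations (white/other coefficient sets only, since the emulated cohorts are
almost exclusively Caucasian; the guideline's worked example, 2.1% for
women, ≈5.3% for men, passes), and low-risk-region SCORE (fatal CVD only;
its test vectors are regression values computed at transcription time and
documented as such inside the file). Cholesterol unit conversion uses
38.67 mg/dL per mmol/L. Because heart-failure outcomes are not collected in
all emulated centers, predictions from a composite-endpoint calculator can
be scaled by a user-supplied outcome-subset fraction (proportional on the
probability scale); the fraction must be supplied, there is no default.
A QRISK-style external calculator can be plugged in as another YAML file;
none is shipped.

## The synthetic-data generator

The generator exists so every stage is exercisable with known ground truth.
It emulates, per center: subject counts and marginal event rates of the
13-center study (0.1–1.8 per 100 person-years), per-center mean follow-up
(1.6–8.4 years, from published person-years/n — this heterogeneity is what
makes the pooled person-year-weighted rate ≈1.3 exceed the subject-weighted
mean of center rates ≈1.18), covariate marginals shaped like the published
baseline table (age 55.3 ± 14, 24% male, 21% current smokers, TC 5.2 ± 1.1
mmol/L, etc.), a single latent disease-activity factor inducing realistic
correlation among DAS28ESR, HAQ, joint counts, VAS and inflammatory markers,
hypertension diagnosis correlated with measured SBP but acting on the
hazard through the diagnosis (the blood-pressure measurements themselves
carry no direct effect, mirroring the study's observation that measured
pressures did not predict), Friedewald-consistent LDL, and TC:HDL always
derived from TC and HDL.

Event times are exponential per cohort by default (Weibull shape
configurable); proportional hazards is the only structure the emulated
analysis assumes, and no time-to-event law is published. The subject hazard
is h0_c · exp(β′(x − x_ref)) with the published Model A coefficient set as
default truth. h0_c is either set from a target 10-year baseline survival or
calibrated by root-finding so the expected marginal event rate under the
censoring process matches the target (using E[events] = λ·E[exposure],
exact for constant hazards). Censoring is uniform administrative entry over
an accrual window plus independent exponential dropout (0.03/y); when a
cohort specifies a target mean follow-up, the window is solved from it.
The censoring process is a stand-in: nothing about real accrual patterns is
published beyond mean follow-up.

Missingness: the default plan blanks 75% of lipids in two designated
centers (Nijmegen and Spain — the two centers are not named in the source;
these two hold 27.6% of subjects, so ≈20% of lipid data is missing overall,
matching the published figure), assigns the block-missing RA characteristics
to fixed centers (CRP absent in 1, DAS28ESR in 1, joint counts in 2, patient
VAS in 4, physician VAS in 8, HAQ in 3), and adds modest scattered
missingness. MCAR masks uniformly; MAR scales the masking probability with
age and sex — deliberately conditioned only on always-observed covariates so
imputation remains testable. The derived lipid ratio always follows its
parents' missingness.

What passing tests on this generator do **not** show about real data: no
country- or healthcare-system effects, no treatment-by-indication dynamics,
no secular trends, no referral bias, no informative censoring, no
measurement error or assay harmonization problems, and covariate
correlations beyond the single latent factor (and the SBP–hypertension
link) are absent. Recovery of generating coefficients demonstrates the
estimator works, not that the published coefficients are right for any real
population.

## Problem sizes and numerical conventions

Simulation-based checks use the study's own scale where that is what is
being claimed (n ≈ 5,638–6,000 subjects, 10-fold CV, m = 5–10 imputations;
50 replicates for coefficient coverage, 20 for selection replication, 500
for the calibration-test type-I error, n = 10,000 for SIR
self-consistency). Follow-up truncation at 12 years uses a closed boundary
(an event at exactly 12.0 years counts). Per-cohort rate tables are computed
on untruncated follow-up (matching the published person-years), model fits
on truncated data. Missing prior-CVD flags are treated as no history, with
a logged warning. Hazard-ratio display rounds to 2 decimals. The IPW
cohort-membership model is a multinomial logit on the traditional CVD risk
factors with stabilized weights (the upstream procedure is not specified
beyond "inverse probability weighting"; the model family is our choice).

## Known limitations

- The Noether-type CI for Harrell's c ignores pair correlation.
- Linear-in-time hazard scaling for published single-horizon calculators is
  a convention, not an estimate of their time profile.
- The global PH statistic is a sum of marginal tests, not the joint test.
- MICE with PMM cannot extrapolate outside the observed donor range.
- The lasso CV standard error follows the per-fold deviance convention;
  alternatives (e.g. per-event weighting) shift the 1-SE choice slightly.
- Wald 95% intervals from fits at the study's event count (~400–650 events)
  show mild undercoverage (≈91–95% per coefficient in the coverage study
  the acceptance suite runs), a known finite-sample property of Cox Wald
  inference with skewed covariates.
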