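# Methods

This note documents the models, defaults and design choices behind the
package: the synthetic CKD cohort generator, the cohort-preparation rules, the
two-step parametric g-formula, and the validation studies the test suite runs.

## Estimands and strategies

All analyses work on person-interval data with 6-month intervals
(182.625 days), interval *k* covering months [6k, 6k+6). Six treatment
strategies are compared: the **natural course** (treatment initiation drawn
from the fitted clinician model; the reference), four **threshold rules**
"initiate urate-lowering therapy once current sUA ≥ τ" for τ ∈ {7, 8, 9, 10}
mg/dl, and **never treat**. Threshold rules are *initiation* rules: therapy is
absorbing, mirroring how the treatment model is fitted (initiation only, no
discontinuation); a strict on/off variant is not implemented.

For mortality the estimand is the 22-year cumulative risk under elimination of
ESKD as a competing process ("net risk", 1 − ∏(1 − h_death)); for ESKD it is
the cumulative incidence with death as a competing event,
∑ₖ S_{k−1}(1 − h_death,k) h_eskd,k, death drawn first within an interval. A
`competing_death=False` switch censors at death instead. Contrasts are risk
ratios (3 decimals) and risk differences in percentage points (2 decimals,
half-even rounding) versus the natural course, at horizons of 5, 10, 15 and 22
years.

One visible consequence of the net-risk choice: the nonparametric observed
mortality benchmark is a product-limit that censors at ESKD. Because ESKD and
death share risk factors (creatinine, age), that censoring is informative and
the product-limit sits ≈2 percentage points *below* the ESKD-eliminated risk at
22 years on the default cohort. The natural-course calibration check therefore
uses the default 2%p tolerance for ESKD (where estimator and estimand match,
observed gap ≈0.2%p) and documents the expected positive offset for death.

## Synthetic cohort generator

The generator is the ground-truth data-generating process and is deliberately
built from exactly the model families the fitting step assumes, so that on
fully observed data the fitted system is correctly specified:

* **Baseline** (n = 27 260 by default): age ~ N(51.0, 15.9²) clipped to
  [18, 95]; 49.3% male; BMI ~ N(24, 3.8²) with 31% missing at random;
  diabetes/hypertension/dyslipidemia prevalences 28.0/47.8/25.8%; log sCr ~
  N(0, 0.45²) (median 1.0 mg/dl, right-skewed); sUA ~ N(5.97, 2.0²) floored at
  1.5 — the baseline urate doubles as the patient's long-run set-point;
  albumin, hemoglobin as baseline-only labs; an albuminuria marker makes
  preserved-eGFR patients CKD-eligible through kidney damage.
* **Dynamics** (lag-1, per interval): sUA regresses toward its set-point
  (ρ = 0.75) with a creatinine pull (0.30 × log sCr) and a treatment effect of
  −0.5 mg/dl per interval, i.e. −2.0 mg/dl at steady state — a typical
  on-therapy reduction; Gaussian noise SD 0.8, floor 0.5 mg/dl. log sCr is an
  AR(0.9) with drift and an sUA-progression term (0.0035 per mg/dl per
  interval), noise SD 0.08. Diabetes, hypertension and dialysis are absorbing
  logistic incidences (dialysis driven by creatinine). An optional quadratic
  sUA term injects mild misspecification for robustness studies.
* **Prescribing** (natural course): per-interval initiation log-odds
  −10.36 + 0.780 × sUA − 0.025 × k. These coefficients were calibrated with
  `scripts/tune_generator.py` so that the natural course reproduces the
  emulated cohort's prescribing pattern: ≈5 360/27 260 ever treated, median
  sUA 9.0 mg/dl at initiation (quartiles ≈7.7–10.3), median 5 years to
  initiation.
* **Hazards** (current-interval state): pooled logistic hazards for death
  (age, sUA, log sCr, dialysis, treatment; intercept −9.78) and ESKD (strongly
  creatinine-driven; intercept −7.08), death preceding and precluding ESKD
  within an interval. Intercepts were calibrated so the *observed* 22-year
  risks after censoring are ≈25.6% (death) and ≈20.5% (ESKD). Optional
  stratum-specific treatment effects (baseline eGFR < 60) support
  effect-modification studies.
* **Observation layer**: staggered enrollment over 18 calendar years with
  administrative censoring at 22 years of data collection; one lab visit per
  interval with probability 0.8 (interval 0 always measured); day-stamped
  labs, comorbidity onset days, prescription episodes and events; optional
  contamination fractions plant prior-ULA exposure, early outcomes,
  non-CKD and ESKD-at-enrollment patients to exercise the eligibility filters
  (all default to 0 — the default cohort represents the post-eligibility
  population).

Randomness uses one master seed with a deterministic stream per
(interval, variable); patient *i* always consumes the *i*-th draw, so
regeneration is byte-identical and growing `n_patients` never reshuffles
earlier patients.

**Counterfactual oracle.** Covariate dynamics do not depend on event
occurrence, so the generator computes true strategy-specific risks by
simulating covariate paths for ≥10⁵ independent patients under the forced
strategy and accumulating the hazards analytically (rather than drawing
events), which is exact for the estimands above and has lower Monte Carlo
variance than event counting.

**What the generator does not emulate**: ICD-code streams, drug/dose
granularity, visit-frequency dependence on disease severity, measurement
error in labs, loss to follow-up correlated with health, and
discontinuation of therapy. Passing tests therefore demonstrate correctness
of the estimation machinery under a faithful-but-idealized data process, not
robustness to every real-EMR pathology.

## Cohort preparation

Applied in order, all deterministic:

1. **Eligibility**: retain adults meeting the CKD definition (baseline
   eGFR < 60 sustained, or albuminuria marker); remove ESKD at enrollment,
   outcomes within 3 months (event day < 90), and any urate-lowering
   prescription overlapping the [−30, +90] day enrollment window. Each patient
   is counted under the first matching rule; the tally must reconcile exactly.
2. **eGFR**: 2009 CKD-EPI creatinine equation; the race coefficient is fixed
   at 1 (East-Asian cohort), a documented constant.
3. **ULA status**: episodes are merged and a patient is "prescribed" from the
   first interval by whose end cumulative covered days strictly exceed 180;
   absorbing; dosages ignored.
4. **Discretization**: one row per patient-interval; last lab measurement in
   an interval wins; events go to the interval containing their day (boundary
   days to the later interval); follow-up ends at the event or censoring day.
5. **LOCF**: missing sUA/sCr carried forward, leading gaps filled from
   baseline labs; observability flags are preserved. Baseline BMI missingness
   is median-imputed with an indicator column (LOCF applies only to the
   time-varying labs).
6. **Gap censoring**: a run of more than four consecutive intervals with
   *neither* lab measured (24 months) censors the patient at the end of the
   fourth unmeasured interval; a switch tightens this to "either lab
   missing". The censoring instant is a convention: the emulated design
   states the window, not the instant.

## Model fitting

Every component conditions on the baseline covariate set (age, sex, BMI +
missingness indicator, diabetes, hypertension, dyslipidemia, baseline log
sCr/sUA/albumin/hemoglobin), the relevant time-varying values, and a
restricted natural cubic spline in the interval index (three interior knots;
the basis spans a linear trend, so the generator's linear time effects are
nested). Covariate models use lag-1 predictors on rows k ≥ 1 (k = 0 rows use
baseline values as lags); absorbing binaries are fitted on at-risk rows only,
with predictions for already-absorbed rows equal to 1 by rule; the treatment
model conditions on current-interval labs (the clinician sees today's values)
among the never-treated; outcome models are discrete-time risk sets with
current-interval state. Dialysis enters only the mortality analysis — in the
ESKD analysis it is nearly collinear with the outcome — and the ESKD analysis
fits an additional death hazard as the competing event. Lag depth is 1
throughout, matching the generator; no variable selection is performed.

Gaussian components are least-squares fits (statsmodels OLS; QR with a
pseudo-inverse fallback for rank-deficient bootstrap resamples). Logistic
components use an in-package damped-Newton maximizer with a 10⁻⁸ ridge on the
Hessian and step-halving — several times faster than generic IRLS across the
thousands of bootstrap refits, and verified against statsmodels GLM to ~10⁻⁸
in the tests. All-0/all-1 logistic responses return a constant predictor with
a warning instead of a divergent intercept. Censoring is treated as ignorable
given covariates; no censoring model is fitted.

## Simulation engine

`mc_size` pseudo-subjects (default 20 000) are resampled with replacement from
the analysis cohort's baseline rows. Per interval: draw sUA and log sCr from
their fitted models (sUA floored at 0.5 mg/dl, matching the generator's
support), update the absorbing flags, apply the strategy's treatment decision
to the *current* urate value, then accumulate the outcome hazards. The natural
course draws treatment from the fitted initiation model and does not simulate
censoring (interventions abolish it; the observed-vs-simulated comparison is
the calibration check). Simulations are seeded and reproducible; risk curves
are nondecreasing by construction and validated on every run.

## Inference

Confidence intervals are percentile bootstrap over patient-level resamples
(preserving within-patient correlation): each replicate refits every component
and resimulates every strategy; non-convergent replicates are dropped and
counted, with >10% failures an error. B = 1000 is the full-run default; the
validation suite uses B = 200 for runtime. The time-varying Cox comparator is
a pooled logistic discrete-time approximation (current treatment, lag-1
covariates, spline in k) whose treatment coefficient is reported as a hazard
ratio with a Wald CI — intentionally the feedback-confounded benchmark; a
partial-likelihood oracle guards the approximation in the tests.

## Validation studies and problem sizes

The end-to-end suite (tests/test_acceptance.py) runs, with fixed seeds:

1. **Generator calibration** — the full default cohort (27 260 × 44); each
   printed summary within 3 Monte Carlo SEs (medians and product-limit risks
   use patient-bootstrap SEs).
2. **Oracle equivalence** — fully observed cohort of 20 000, mc = 20 000, all
   six strategies × both outcomes vs forced-strategy truth at 10⁵ patients,
   within 3 combined MC SEs.
3. **Null safety** — a zero-effect generator: point RDs at n = 10 000 within
   3 MC SEs of zero, and bootstrap coverage of zero in ≥90% of 20 replicate
   studies (n = 150 each, B = 200, mc = 400 — sizes chosen to keep the full
   suite a desk-scale run; coverage is size-free under the null).
4. **Dose ordering** — protective generator, n = 8 000: risks ordered
   τ7 ≤ τ8 ≤ τ9 ≤ τ10 ≤ never within MC error.
5. **Confounding demonstration** — a confounding-by-indication generator
   (initiation sharply triggered by current sUA, benefit wholly mediated
   through urate lowering): the lag-adjusted Cox HR sits near the null while
   the true τ7-vs-natural RD is ≈ −6.9%p and the g-formula recovers it.
6. **Boundary exactness** — CKD-EPI continuity at the κ knot, the discrete
   risk identity on enumerated paths, LOCF idempotence, the 180-day and
   24-month boundaries, threshold inclusivity at sUA = τ.

## Known limitations

* The natural-course death calibration offset discussed above.
* Coefficient tuning targets medians and totals; the full distribution of sUA
  at initiation is matched only approximately (first quartile ≈7.7 vs the
  emulated 8.0 mg/dl).
* Prescription episodes are reconstructed so that the >180-day rule reproduces
  the generator's treatment timing; for the rare initiations in the first
  year the enrollment washout clamps the episode start and the derived status
  can shift by one interval.
* The bootstrap treats the Monte Carlo standardization error as part of the
  replicate noise; at small mc_size this widens CIs slightly (conservative).
* No discontinuation, adherence, dose, or per-agent modeling.
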