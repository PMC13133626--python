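# Data dictionary

## Raw observed bundle (written by `urategf simulate`, read by `prep`)

### raw_patients.csv — one row per patient
| column | description |
|---|---|
| patient_id | integer patient key |
| age | age at enrollment, years |
| male | 1 = male, 0 = female |
| bmi | body-mass index, kg/m² (NaN when unmeasured) |
| bmi_missing | 1 if BMI unmeasured at baseline |
| dm0, htn0, dyslip0 | baseline diabetes / hypertension / dyslipidemia flags |
| scr0, log_scr0 | baseline serum creatinine, mg/dl (and its log) |
| sua0 | baseline serum urate, mg/dl |
| albumin0, hgb0 | baseline serum albumin (g/dl), hemoglobin (g/dl) |
| egfr0 | baseline 2009 CKD-EPI eGFR, ml/min/1.73 m² |
| albuminuria | kidney-damage marker (CKD-qualifying when eGFR ≥ 60) |
| dm_onset_day, htn_onset_day, dialysis_onset_day | day of incident flag (0 if at baseline, NaN if never) |
| event_type | "death", "eskd" or "none" (first observed event) |
| event_day | day of the event from enrollment (NaN if none) |
| censor_day | administrative censoring day (NaN if an event occurred) |
| eskd_at_enroll | ESKD already present at enrollment (eligibility filter) |

### raw_labs.csv — one row per lab visit
| column | description |
|---|---|
| patient_id | patient key |
| day | measurement day from enrollment |
| sua, scr | serum urate / creatinine at that visit, mg/dl |

### raw_rx.csv — one row per urate-lowering prescription episode
| column | description |
|---|---|
| patient_id | patient key |
| start_day, end_day | covered period, days from enrollment (negative start = pre-enrollment exposure) |

## Analysis table (person_intervals.csv)

One row per patient per 6-month interval k (interval k = months [6k, 6k+6)),
contiguous from k = 0 until the first of event/censoring.

| column | description |
|---|---|
| patient_id, k | keys |
| sua, scr, log_scr | time-varying labs after LOCF imputation |
| egfr | CKD-EPI eGFR from current sCr and attained age |
| dm, htn, dialysis | absorbing time-varying comorbidity flags |
| tx | urate-lowering treatment status (>180 cumulative days rule; absorbing) |
| event_death, event_eskd, censored | terminal-state flags (≤1 per row, last row only) |
| measured_sua, measured_scr | pre-LOCF observability flags |
| age … egfr0 | baseline covariates replicated per row (see raw_patients) |

## Fitted model sets (model.json)

JSON document with the outcome, component order, spline knots, baseline
covariate list and, per component: family (gaussian/binomial), predictor term
names, coefficients, residual SD (gaussian), standard errors, row count, and a
degenerate constant value when the response was all-0/all-1.
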