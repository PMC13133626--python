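# urate-gformula

Parametric g-formula pipeline for studying **when to start urate-lowering
therapy (ULT) in chronic kidney disease (CKD)**.

In CKD cohorts, serum urate (sUA) and serum creatinine (sCr) are time-varying
confounders affected by prior treatment: high urate prompts clinicians to
prescribe a urate-lowering agent, the drug lowers subsequent urate (and, through
it, slows creatinine rise), and both labs drive the hazards of death and
end-stage kidney disease (ESKD). Conventional time-varying Cox regression is
biased in this feedback setting. The parametric g-formula (g-computation)
handles it in two steps:

1. **Fit** pooled parametric models on person-interval data (6-month intervals):
   linear-Gaussian models for sUA and log sCr given the previous interval's
   state, logistic incidence models for diabetes, hypertension and dialysis,
   a logistic treatment-initiation model, and pooled logistic discrete-time
   hazards for the outcomes.
2. **Simulate** pseudo-subjects forward from baseline under explicit strategies
   — the *natural course* (treatment drawn from the fitted initiation model),
   *threshold rules* "initiate once sUA ≥ τ mg/dl" for τ ∈ {7, 8, 9, 10}
   (absorbing), and *never treat* — and standardize: for per-interval hazards
   h₁,…,h_K along a simulated history, the cumulative risk is
   1 − ∏ₖ(1 − hₖ), averaged over pseudo-subjects (for ESKD, the cumulative
   incidence with death as a competing event). Contrasts are reported as risk
   ratios and risk differences versus the natural course, with patient-level
   percentile-bootstrap confidence intervals.

Because real EMR cohorts of this kind are not public, the package ships a
first-class **synthetic cohort generator** with exactly this
treatment-confounder feedback structure, calibrated to the published summary
characteristics of a large Korean CKD cohort (n = 27 260, 22 years of 6-month
intervals, ≈20% ever treated, median sUA 9.0 mg/dl at initiation, median 5
years to initiation, observed 22-year risks ≈25.6% death / ≈20.5% ESKD). The
generator doubles as a ground-truth oracle: forced-strategy simulation yields
the true counterfactual risks the g-formula must recover.

## Worked example

```python
import urate_gformula as ug

cfg = ug.default_config(n_patients=4000, seed=11)   # scaled-down cohort
gen = ug.CohortGenerator(cfg)
baseline = gen.sample_baseline()
trajectories = gen.simulate_trajectories(baseline)
raw = gen.apply_observation_process(trajectories, baseline)

prep = ug.CohortPreprocessor(n_intervals=cfg.n_intervals)
table = prep.fit_transform(raw)       # eligibility, 6-mo intervals, LOCF, gap censoring

gf = ug.ParametricGFormula(outcome="death", mc_size=10000, seed=1).fit(table)
obs = ug.observed_risk_nonparametric(table, "death", cfg.n_intervals)
print(f"observed 22-y mortality risk: {100*obs.risk_at(44):.1f}%")
for c in gf.estimate_contrasts(horizons_years=(22,)):
    print(f"{c.strategy:8s} risk {c.risk:5.1f}%  RR {c.rr:.3f}  RD {c.rd:+.2f}%p")
```

prints

```
observed 22-y mortality risk: 23.3%
natural  risk  25.7%  RR 1.000  RD +0.00%p
tau10    risk  25.6%  RR 0.997  RD -0.07%p
tau9     risk  24.5%  RR 0.955  RD -1.16%p
tau8     risk  23.2%  RR 0.905  RD -2.45%p
tau7     risk  21.9%  RR 0.854  RD -3.74%p
never    risk  27.2%  RR 1.057  RD +1.48%p
```

Reading the table: the natural course (clinician-driven prescribing, the
reference) implies a 25.7% standardized 22-year mortality risk; initiating
therapy whenever sUA reaches 7 mg/dl would lower it by 3.74 percentage points,
while never treating would raise it by 1.48 — the dose-ordered pattern expected
when earlier treatment is protective. (At this reduced cohort size the Monte
Carlo error on each risk is a few tenths of a percentage point.)

`ug.bootstrap_cis(table, B=1000, ...)` adds percentile CIs by refitting and
resimulating on patient-level resamples; `ug.fit_tv_cox(table, "death")` fits
the (feedback-confounded) time-varying Cox comparator; `ug.subgroup_analysis`
refits within eGFR/age/BMI strata. The same pipeline is scriptable from the
shell via the `urategf` command (`simulate`, `prep`, `fit`, `gformula`,
`report`).

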