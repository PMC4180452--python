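# gompertzle

Life-expectancy estimation for older adults from the Lee mortality index,
via Gompertz proportional-hazards survival models.

## The problem

Mortality-risk indexes for community-dwelling adults over 50 — the Lee
index is the canonical one — summarise twelve patient-level risk factors
(age band, sex, six comorbidity/behaviour items, four functional items)
into a point score that stratifies patients into 15 risk groups. The index
predicts *mortality risk at a fixed horizon* ("28% at 4 years"), which is
hard for patients and clinicians to act on. What clinical guidelines
actually ask for is *life expectancy* ("7.3 years"), because preventive
interventions such as cancer screening only help patients likely to
outlive the intervention's lag time to benefit.

The bridge between the two is the Gompertz law of human mortality: adult
death rates rise exponentially with time, doubling over a roughly fixed
interval. Treating each risk group as a subpopulation obeying that law,
the hazard for a person in group *g* is

```
h_g(t) = λ_g · exp(γ t),        λ_g = exp(β₀ + β_g)
```

with one shared shape γ (1/years; ln 2 ⁄ γ is the mortality doubling time)
and a group-specific rate acting proportionally — the score enters as a
categorical covariate, 14 dummy contrasts against the 0-point group. The
model is fitted to right-censored follow-up (~10 years) by maximum
likelihood and then inverted in closed form:

```
S(t) = exp(−(λ_g/γ)(e^{γt} − 1)),      t_p = ln(1 − (γ/λ_g) ln(1−p)) / γ
```

giving each group's time to 25%, 50% (median life expectancy) and 75%
mortality — including extrapolation beyond the observed follow-up, which
is exactly what a fixed-horizon risk index cannot do.

## What the package provides

- `scoring` — the 12-item Lee point score and 15-level risk group, for
  single profiles or delimited tables.
- `gompertz_survival` — Gompertz hazard/survival/quantile functions,
  right-censored log-likelihood, deterministic profile-likelihood MLE with
  the risk group as a categorical proportional-hazards covariate, and
  AIC/BIC comparison against Weibull and exponential alternatives.
- `life_expectancy` — per-group survival quantiles; percentile-bootstrap
  95% confidence intervals; 50% prediction intervals for an individual's
  survival time; reconstruction of the full model from a published
  quantile table (re-calibration from summary data alone).
- `validation` — Kaplan–Meier curves per group (via lifelines), Harrell's
  c of the point score, fixed-horizon Hosmer–Lemeshow calibration tests,
  and predicted-vs-observed curve export.
- `cohort` — synthetic cohorts with known truth: the published point-score
  distributions of the development (n = 11 701), internal-validation
  (n = 8 009) and English external-validation (n = 7 042) cohorts,
  per-group Gompertz survival and administrative censoring.
- `cli` — `gompertzle score | simulate | fit | predict | validate |
  recalibrate` for shell use; the library API is the primary surface.

## Worked example

`examples/score_patient.py` scores the index's canonical patient — a
77-year-old man with heart failure and difficulty walking several blocks —
and reads his life expectancy off the reconstructed published model:

```
Lee points: 10  (risk group 10)
time to 25% mortality:   3.8 years
median life expectancy:   7.3 years
time to 75% mortality:  11.3 years
note: extends beyond the 10-year validated follow-up (extrapolated)
```

4 points for age 75–79, 2 for male sex, 2 for heart failure and 2 for the
walking limitation put him in the 10-point group; the Gompertz model for
that group crosses 50% survival at 7.3 years, with the central half of
such patients dying between ~3.8 and ~11.3 years. The other example
scripts fit the model to a simulated cohort and print the full 15-group
life-expectancy table with confidence and prediction intervals
(`fit_and_predict.py`), validate a model against an independent cohort
(`validate_model.py`), and rebuild the model from a published quantile
table, reproducing its held-out third-quartile column to print precision
(`recalibrate_from_table.py`).

## Limitations

Predictions beyond the 10-year follow-up are extrapolations of the fitted
hazard; the model is calibrated to US community-dwelling adults and is
expected to need re-calibration elsewhere (the reconstruction-from-
quantiles path exists for exactly that); and synthetic cohorts draw
survival from the group-level model, so they carry no within-group
heterogeneity beyond it. See `docs/methods.md` for the full model account.
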