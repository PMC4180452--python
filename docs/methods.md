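# Methods

## Model

Each of the 15 Lee-index risk groups is treated as a homogeneous
subpopulation whose mortality follows a Gompertz law: hazard
`h_g(t) = λ_g exp(γt)` with a single shared shape `γ` (units 1/year) and a
group-specific rate `λ_g > 0` entering proportionally,
`λ_g = exp(β₀ + β_g)` with group 0 as reference. Time `t` is years since
baseline. The implied survival and quantile functions are

    S_g(t) = exp(−(λ_g/γ)(e^{γt} − 1))
    t_p    = ln(1 − (γ/λ_g) ln(1 − p)) / γ

with the exponential limits `S = e^{−λt}`, `t_p = −ln(1−p)/λ` as `γ → 0`.
All three are evaluated through `exprel`/`log1p` so the `γ → 0` branch is
exact to machine precision; the quantile falls back to the exponential
form when `γ·(−ln(1−p))/λ` is below 1e−15, where the correction is
sub-ulp. For `γ < 0` the cumulative hazard plateaus at `−λ/γ`; quantiles
beyond the attainable mortality fraction raise a dedicated plateau error
rather than returning NaN.

Assumptions worth stating: proportional hazards across groups with a
common shape (group curves never cross); homogeneity within group; and
that the exponential hazard growth observed inside the ~10-year follow-up
continues beyond it. Quantiles past the follow-up horizon are therefore
labelled `extrapolated` in every output.

## Fitting

The right-censored log-likelihood is

    ℓ = Σ_deaths [ln λ_g + γ t_i] − Σ_all (λ_g/γ)(e^{γ t_i} − 1).

At fixed `γ` the rate MLE is closed form per group — deaths over
Gompertz-transformed exposure, `λ̂_g = d_g / Σ_i t_i·exprel(γ t_i)` — so
the fit profiles `γ` and solves a one-dimensional maximisation with
Brent's method from a fixed bracket around 0. This is deterministic,
needs no starting values for the 15 rates, and makes thousand-replicate
bootstraps cheap. The same profiling fits the Weibull
(`H = λ_g t^p`, exponent optimised on the log scale) and exponential
comparison families; AIC and BIC use `k` = number of groups present plus
one shape (16 for the full Gompertz/Weibull, 15 for the exponential).
The Gompertz fit was cross-checked against an independent R
implementation (flexsurv) on a simulated cohort: shape agreement to
~5e−5, log-likelihood to printed precision.

Edge conventions: `γ` is unconstrained, with a warning when the estimate
is negative (high quantiles may be unattainable); deaths recorded at time
zero are offset by half a day (0.0014 y) with a warning; a group observed
without events gets rate 0 and a warning — its exposure still informs
nothing beyond that, and its quantiles are undefined.

## Intervals

**95% confidence intervals** use the nonparametric bootstrap: resample
persons with replacement, refit, take percentile intervals of each
group's quantiles (percentile rather than normal or BCa — the simplest
defensible construction, recorded in output metadata). Replicates whose
refit fails are dropped and counted, with a warning above 10%; a group
whose quantiles are undefined in a particular resample (no deaths drawn)
contributes NaN for that replicate and is excluded group-wise. Default
B = 1000.

**50% prediction intervals** describe an individual, not the population
median: for each bootstrap replicate, 100 individual survival times are
drawn from that replicate's fitted group distribution by inverse-CDF
sampling, and the interval is the central 50% of the pooled draws. This
mixes parameter uncertainty with between-person variability; with no
sampling uncertainty it collapses to the model's own (t25, t75) band, and
it tightens toward that band as the cohort grows. Other central levels
generalise through the `level` argument.

All randomness flows from a single user-supplied integer seed, recorded
in outputs.

## Reconstruction from a published quantile table

Any Gompertz distribution satisfies
`(e^{γ t50} − 1)/(e^{γ t25} − 1) = ln(0.5)/ln(0.75) ≈ 2.4094`
for its 25% and 50% mortality times. Given a published table of
(t25, median) pairs per group, the shared shape is the least-squares
minimiser of the ratio residuals over all pairs, and each rate follows
exactly from its median, `λ_g = γ ln 2 / (e^{γ t50_g} − 1)`. Residuals on
the ratio scale make short-time groups — whose printed quantiles carry
the heaviest relative rounding and whose ratio is nearly shape-
insensitive — contribute little, which is the intended weighting. On the
built-in published table this yields γ ≈ 0.1123 (hazard doubling every
~6.2 years) and reproduces the table's third-quartile column, which the
reconstruction never sees, to its 0.1-year print precision. The same
routine is the re-calibration path for any population with such a summary
table, and is exact (1e−8) on noiseless input.

## Validation components

*Kaplan–Meier* curves per group come from lifelines' product-limit
estimator (censorings at an event time remain at risk for it), wrapped in
a step-function container with "not reached within follow-up" quantile
semantics.

*Harrell's c* uses the point score as the predictor (any strictly
monotone transform gives the same value). Usable pairs have distinct
times with the shorter one an observed death; concordance means the
higher score died first; score ties count one half; time-tied pairs are
excluded. The implementation sweeps event times once, maintaining
per-score counts of subjects still under observation, so it is exact and
O(n·n_scores) — it matches exhaustive pair enumeration on small sets and
lifelines' `concordance_index` on tie-free data bit for bit.

*Hosmer–Lemeshow* calibration is the fixed-horizon grouped form on the 15
point groups (the natural grouping here): observed deaths by horizon `h`
are `n_g·(1 − S_KM(h))` so censoring is respected, expected deaths are
`n_g·(1 − S_model(h))`, and the statistic is `Σ (O−E)²/(E(1−E/n))`,
referred to chi-square with G−2 degrees of freedom when the model was fit
to the same data and G when validating externally. Groups with expected
deaths below 1 merge into a neighbour with a warning. No exact published
variant exists for this setting; the implementation is method-consistent
rather than bit-identical to any particular software, and simulation
shows its size is near nominal (rejection rate 3.4% at α = 5% over 500
model-generated cohorts of n = 8000) with essentially complete power to
detect a twofold rate error at that size.

## Synthetic cohorts

The generator emulates the structure of the published study populations:
group membership either multinomial or with the exact published per-group
counts (development 11 701, internal validation 8 009, external 7 042),
survival drawn from each group's Gompertz distribution by inverse CDF
(defaults: the reconstructed published model), administrative censoring
at the cohort's follow-up horizon (10 y US, 8 y England), and optional
uniform dropout (off by default — deaths in the source studies were
registry-ascertained). A factor-level mode draws the 12 items
independently from published marginal prevalences and scores them; since
real risk factors co-occur, this narrows the score distribution relative
to the published joint, so score-level mode is the default everywhere
that distributional fidelity matters.

What synthetic data cannot show: within-group heterogeneity (each group
is exactly Gompertz by construction), real-world deviations of group
hazards from the fitted law inside follow-up, and survey-design features
(weights, clustering, interview timing). Passing tests therefore
demonstrate estimator correctness and internal consistency, not clinical
transportability. A concrete consequence: the concordance of the point
score on cohorts simulated from the reconstructed model under 10-year
censoring is ≈ 0.816, a little above the published real-data value
(0.790), because the real cohort's observed group survival deviates
modestly from the fitted curves while the simulation reproduces them
exactly.

## Test-suite problem sizes

Simulation-backed tests use sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: parameter recovery at n = 20 000 × 50
replicates; family selection at n = 10 000 × 50; calibration size at
n = 8 000 × 500 and power at n = 8 000 × 40; bootstrap coverage at
n = 2 000 with B = 120 over 60 outer replicates (coverage checked within
3 binomial SE); discrimination at the development cohort's exact size
over 20 seeds.
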