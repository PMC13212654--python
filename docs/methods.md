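# Methods

## The model

`salmo_mo2` models the mass-specific oxygen consumption rate of seawater-adapted
Atlantic salmon post-smolts as a product of three effects,

    MO2 = a · W^b · c^T · d^U

with MO2 in mg O2 kg⁻¹ h⁻¹, body weight W in kg, water temperature T in °C and
relative swimming speed U in body lengths s⁻¹. The coefficients have direct
physiological readings: `a` is the rate of a 1 kg fish at 0 °C holding still,
`b` is the mass-specific allometric exponent (negative: smaller fish consume
more oxygen per kg), `c` is the per-degree multiplier (so Q10 = c¹⁰), and `d`
the per-BL/s multiplier. The packaged reference sets are the refined
estimate `(79.7, −0.14, 1.04, 1.63)` from seven group swim-tunnel
respirometry experiments on a modern domesticated strain, and the legacy
Grøttum & Sigholt (1998) set `(61.6, −0.33, 1.03, 1.79)`.

The exponential forms for T and U are empirical conveniences that hold only
below the physiological plateaus: aerobic metabolism flattens near the upper
thermal tolerance (~23 °C) and near the critical swimming speed, where
anaerobic pathways take over. The data-filtering rules and the prediction
guardrails both encode exactly these limits.

## Data model and filters

One entry is a replicate-aggregated observation: the unique combination of
study, treatment group, W, T and U, with MO2 averaged (unweighted) over the
2–6 affiliated replicate trials. `aggregate_replicates` collapses per-trial
records; group sizes are deliberately not used as weights, the simplest
reading of an unweighted compilation.

Two filter stages are separated because they answer different questions:

* inclusion criteria (environmental/husbandry comparability): full-strength
  seawater, normoxia, ≥ 3 weeks of thermal acclimation, healthy fish, fed
  through acclimation and fasted only overnight. Each removed entry is
  attributed to the first violated rule in that order.
* model-assumption filters (validity of the exponential forms): entries at
  ≥ 23 °C and entries at 100 % of the group critical swimming speed. The
  23 °C exclusion is implemented as a configurable `temp_cutoff` applied as
  `≥` rather than a named-group removal, which makes the rule reusable on
  other compilations. Entries without a recorded `pct_ucrit` (sustained-speed
  tests) are never touched by the speed rule — a missing U_crit fraction is
  not evidence of plateau.

Both filters are idempotent and commute on disjoint rule sets; tests assert
both properties.

## Two-stage estimation

**Stage 1** linearises the model: OLS of ln MO2 on {1, ln W, T, U}
(via statsmodels), back-transformed as a = exp(intercept), b = slope(ln W),
c = exp(slope T), d = exp(slope U). Stage 1 is exact when data follow the
model exactly, and is used only for starting values; rank-deficient designs
raise an error naming the collinear column.

**Stage 2** maximises the exact Gaussian marginal likelihood of a nonlinear
mixed-effects model on the untransformed scale, with an additive random
study intercept: within study i, with basis x_ij = W^b c^T d^U,

    y_i ~ N(a·x_i, σ_u²·x_i x_iᵀ + σ_e²·I).

The random deviation is placed on the intercept a (a_i = a + u_i): it is the
conventional reading of a study-level random effect in this two-stage
tradition and keeps the conditional model linear in u_i. Which coefficient
actually carries the between-study heterogeneity is not identifiable from a
seven-study compilation, so only this variant is implemented.

The rank-one covariance is handled in closed form (matrix determinant lemma
and Sherman–Morrison), so each likelihood evaluation is O(n). The gradient is
analytic (derived from the same rank-one algebra and verified against finite
differences in the test suite), which lets the optimiser reach tight
tolerances cheaply.

Numerical choices:

* parameters optimised as (a, b, ln c, ln d[, γ], ln σ_u, ln σ_e): log-scales
  enforce positivity of c, d and the variance components; b is unconstrained.
* starting values: stage-1 coefficients, σ_u = 10 % of a, σ_e = the stage-1
  residual SD on the natural scale.
* σ_u has an effective floor of 1e−8·a and σ_e of 1e−8·⟨|y|⟩; both are capped
  at 1e6·⟨|y|⟩ so exploratory steps cannot overflow. In noise-free degenerate
  fits σ_e runs to its floor, as expected.
* optimisation by L-BFGS-B with the analytic gradient, then Newton polishing
  (numerical Hessian, backtracking line search) until the gradient ∞-norm
  over free (not bound-active) parameters is < 1e−6, the declared
  convergence criterion. If the plain start does not converge, up to six
  deterministic jittered restarts are tried and the best converged optimum
  kept; this removes occasional degenerate variance spikes (σ_e → 0 with an
  inflated σ_u) without introducing nondeterminism. Non-convergence is
  reported in the result, never raised.
* estimation is plain maximum likelihood, not REML: it matches the default
  of the two-stage tradition this follows and keeps likelihood-ratio tests
  for the interaction screen valid.
* standard errors from the observed information: central-difference Hessian
  of the negative log-likelihood at the optimum (relative step 1e−5, built
  from the analytic gradient), inverted, delta-method-transformed to the
  natural (a, b, c, d) scale. Wald intervals are computed on the optimisation
  scale and back-transformed, so c and d intervals are always positive.
  Profile intervals are not implemented.
* no observation weights: entries count equally regardless of group size or
  replicate count, matching the unweighted compilation.

## Interaction screening

Each two-way product of the predictors (ln W·T, ln W·U, T·U) is added inside
the exponent of the mean function, the model refitted, and the candidate
scored by likelihood-ratio test (χ², 1 df) and ΔAIC. A candidate passes at
p < 0.05 **and** ΔAIC < −2; if several pass, the best is retained only when
its AIC beats the runner-up by more than 2, and a tie retains nothing. The
pass-and-clear-winner rule operationalises "no term statistically supported
over the others" — the original analysis states no numeric criterion, so one
had to be fixed; this one is conservative and deterministic. Simulation
tests check both error rates: per-candidate retention on null data stays
below α + 3 Monte-Carlo SDs (200 replicates), and a planted T×U term ≥ 10×
its SE is retained in ≥ 95 % of 100 replicates.

## Diagnostics and derived quantities

R² = 1 − SSE/SST and RMSE = √(SSE/n) are computed from fixed-effect
(population-level) predictions by default; adjusted R² uses p = 3
predictors. A mixed-model R² is not uniquely defined, so both the prediction
level (population vs conditional, the latter adding posterior-mean study
effects) and p are arguments; RMSE uses 1/n rather than 1/(n−p). The legacy
comparison scores the published legacy coefficients as-is, without refitting,
against the same dataset.

Q10 = c¹⁰. The temperature-sensitivity contrast compares percentage rises
per 10 °C, 100·((Q10_new−1)−(Q10_old−1))/(Q10_old−1); overrides allow
computing it from rounded published Q10 values, which is why 1.34 → 1.45
prints as 32 % while unrounded coefficients give a slightly different number.

Prediction curves carry 95 % bands from the delta method on ln MO2: with
gradient (1/a, ln W, T, U) with respect to (a, b, ln c, ln d), the band is
exp(ln μ ± z·sd), guaranteeing positivity and containment of the point
prediction. A parametric-bootstrap oracle (2000 draws from N(est, vcov))
validates the band width in tests; the delta method is the implementation,
the bootstrap only a check.

## Synthetic data generator

The generator reproduces the statistical structure the estimator assumes,
not fish physiology: seven studies laid out as treatment groups × speed
ladders spanning 0.205–3.38 kg, 3–18 °C and 0.31–2.84 BL/s, yielding exactly
76 refined entries; with plateau rows enabled the raw table has 96 entries of
which 20 violate the model-assumption filters (an eight-row treatment group
at 23 °C plus one 100 %-U_crit row per critical-swim group). Generating
parameters default to the refined coefficient set with σ_u = 8 (≈10 % of a)
and σ_e = 55 in constant-variance mode — σ values chosen so refit residual
scale lands in a realistic range for this kind of data; a proportional mode
(SD ∝ mean) mimics the heteroscedasticity visible at high fitted values.
Negative draws are redrawn rather than clipped, preserving positivity with
negligible bias at these noise levels. Plateau rows are emitted at 0.85× the
exponential extrapolation; the factor is a documented convention, since no
quantitative plateau magnitude is established. Everything is a pure function
of the config seed; per-study intercept draws are recorded in the returned
truth object so recovery tests can condition on them.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: within-group size variation, correlated errors
along a speed ladder (the same fish swim every step), non-Gaussian tails,
temperature- or size-dependent residual variance beyond the proportional
mode, and any real plateau shape. Parameter-recovery results therefore
validate the estimator under its own assumptions, not the biological truth
of the model.

## Guardrailed prediction

Per axis, a request is `in_range` (inside the fitted ranges),
`extrapolated_ok` (outside but physiologically defensible: W in 0.1–6 kg,
T in 0–3 °C, U below 0.31 down to rest) or `extrapolated_caution`
(T in 18–23 °C where predictions are likely mildly inflated; U above
2.84 BL/s where anaerobic recruitment makes the model overestimate; W
outside 0.1–6 kg). Temperature below 0 °C (plasma freezing) or above 23 °C
(upper thermal tolerance) is refused outright — the "~23 °C" cap is resolved
to an inclusive 23.0. Speed has no hard ceiling because U_crit is
population-specific and unknown at prediction time; callers get the caution
flag and the 80–90 % U_crit message instead. A dissolved-oxygen saturation
below 100 % appends a qualitative `hypoxia_caution`; no limiting-oxygen-
saturation arithmetic is attempted.

## Problem sizes and runtime

Simulation-backed tests use the default seven-study structure (76 refined
entries): 200 replicates for parameter recovery and interval coverage, 200
for the screen's null retention rate, 100 for its power, and 500 for the
between-study SD check. One stage-2 fit takes ~20 ms, so the full suite runs
in well under a minute on a single core.

## Known limitations

* Only the additive-intercept random effect is available; no heteroscedastic
  residual models are fitted even though the diagnostics can reveal them.
* Wald (not profile or bootstrap) uncertainty throughout; with seven studies
  the σ_u estimate is itself poorly determined, and interval coverage for
  `a` sits at the lower edge of the nominal range in simulations.
* The sigmoidal plateau alternatives for T and U are intentionally out of
  scope — the filters restrict the data to the exponential regime instead.
* No raw oxygen-trace processing: inputs are already-computed MO2 values.
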