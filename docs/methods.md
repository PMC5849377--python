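# Methods

## Model

The model maps four daily environmental measurements to an expected count
of pediatric respiratory hospitalizations through a Mamdani fuzzy inference
system. Each input is a linguistic variable with exactly two trapezoidal
membership functions that are complementary shoulders: the left shoulder is
1 up to the crossover segment, falls linearly across it, and the right
shoulder mirrors it, so the two memberships sum to one everywhere in the
domain (partition of unity). This guarantees that at least one of the 16
rules fires with positive degree at every input point, so centroid
defuzzification is always well defined under the default configuration.

Default input calibration (all breakpoints overridable via YAML config):

| variable | domain | "favorable" term | "adverse" term |
|---|---|---|---|
| pm10 (µg/m³) | [0, 150] | acceptable (0, 0, 15, 35) | unacceptable (15, 35, 150, 150) |
| no2 (µg/m³) | [0, 130] | acceptable (0, 0, 40, 80) | unacceptable (40, 80, 130, 130) |
| temperature (°C) | [0, 45] | high (22, 32, 45, 45) | low (0, 0, 22, 32) |
| wind (m/s) | [0, 5] | strong (1.8, 2.8, 5, 5) | weak (0, 0, 1.8, 2.8) |

The PM10 crossover (15, 35) is pinned by the calibration requirement that
24 µg/m³ score 0.55 acceptable / 0.45 unacceptable, with the 0.5/0.5
crossover at 25 µg/m³ — readings of 23 and 25 µg/m³, which a crisp
acceptable/unacceptable threshold would separate categorically, differ here
by only 0.1 in membership. The remaining input breakpoints are chosen to
bracket the observed data ranges of the study region with the crossover
near the seasonal swing of each variable.

The output variable (daily hospitalizations, domain [0, 9] matching the
observed count range) has five terms: L (0, 0.9, 1.8), ML (1.8, 2.7, 3.6),
M (3.6, 4.5, 5.4), MH (5.4, 6.3, 7.2) — triangles — and the upper-shoulder
trapezoid H (7.2, 8.1, 9, 9). Equal-width, touching terms are a deliberate
numerical choice: with `max` aggregation the defuzzified centroid is a
mass-weighted average of the clipped consequents, and when the terms have
very unequal masses (for example a narrow L next to a wide M), shifting
activation from one consequent to the next can move the centroid backwards.
With equal term masses the prediction is non-decreasing along each
pollutant axis whenever temperature and wind sit on their shoulder plateaus
(verified on dense 301×301 sweeps at all four high/low × strong/weak
corners). At interior temperature/wind points where both of a variable's
terms are active, small non-monotonic ripples (order 0.03 hospitalizations)
remain and are intrinsic to Mamdani min–max inference with this rule base:
the M consequent is reachable from both pollutant-acceptable and
pollutant-unacceptable antecedents, so its activation is V-shaped along a
pollutant sweep regardless of breakpoint placement.

The 16 rules enumerate every combination of the four binary input terms
once (weights all 1). Consequents follow the severity logic: all-favorable
combinations map to L; a single adverse pollutant maps to ML when
dispersion conditions are good (high temperature, strong wind) and M
otherwise; both pollutants adverse map to M, MH or H as dispersion
deteriorates, with H reserved for the fully adverse corner.

Inference: rule activation is `min` over the antecedent memberships times
the rule weight; each rule's consequent is clipped at its activation (`min`
implication); clipped consequents are combined pointwise by `max`; the
crisp output is the centroid of the aggregated curve.

## Numerical choices

- Centroid integrals use the trapezoidal rule on a uniform 1001-point
  output grid. The aggregated curve is piecewise linear, so the rule is
  exact except in cells containing kinks; measured error against analytic
  clipped-trapezoid centroids is ~1e-5, and 501- vs 5001-point grids agree
  to better than 1e-2 hospitalizations on random activation sets.
- Inputs outside a variable's domain are clamped to the nearest edge with a
  logged warning rather than rejected — monitoring series legitimately
  exceed nominal scales. Non-finite inputs are rejected.
- If no rule fires (impossible under the defaults, possible under
  user-supplied term sets with coverage gaps), inference returns the output
  domain midpoint and emits a `NoRuleFiredWarning`.
- Rows with any missing exposure yield a missing prediction; no imputation,
  so validation statistics only ever see observed days.
- Batch inference is vectorized and chunked so the (days × rules × grid)
  intermediate stays below a few hundred MB regardless of series length.

## Validation procedure

Exposure (or prediction) on day t is paired with the observed count on day
t+lag, lags 0–3; incomplete pairs are dropped and counted. Pearson r is
reported with the two-sided p-value from t = r·√((n−2)/(1−r²)) on n−2
degrees of freedom. Counts are dichotomized at a cutoff of 2 ("up to 2
hospitalizations" delimits the negative class, so positive ⇔ count > 2; an
inclusive variant is available). Each predictor — PM10, NO2, and the model
prediction, all clearly labeled — is scored by ROC AUC, computed as the
trapezoidal ROC integral (equivalently the Mann–Whitney U statistic with
ties counted ½). The 95% CI uses the Hanley–McNeil closed-form standard
error by default because it is deterministic and adequate at these sample
sizes; the DeLong placement-variance estimator is available via
`ci_method="delong"`. CIs are clipped to [0, 1].

## Synthetic-data generator

No public accession exists for the study's hospitalization/monitoring
series, so the generator emulates its documented structure:

- **Pollutants**: concentration = (baseline + annual sinusoid + burn-season
  boost) × unit-mean lognormal noise, clipped to the observed min/max. The
  burn window is day-of-year 182–273 (July 1 – September 30). Baselines are
  set analytically as target mean − duty-cycle × boost, so the expected
  sample mean equals the target (PM10 36.57, NO2 51.35 µg/m³). Defaults:
  PM10 amplitude 8, boost 14, σ 0.5; NO2 amplitude 8, boost 10, σ 0.4 —
  chosen once to approximate the observed SDs (22.1 and 23.5).
- **Temperature**: mean 30.38 °C, annual sinusoid (amplitude 3 °C) peaking
  mid-February — opposed to the dry-season pollutant peak — plus Gaussian
  noise (SD 2 °C), clipped to [11.5, 39.8].
- **Wind**: truncated Gaussian, mean 2.26, SD 0.53 m/s, on [1.1, 4.1].
- **Counts**: Poisson with log λ_t = β₀ + Σ_lag (β_PM[lag]·z_PM10,t−lag +
  β_NO2[lag]·z_NO2,t−lag) − β_T·z_temp,t − β_W·z_wind,t on standardized
  covariates, lag coefficients decaying over 0–3 days (PM10: 0.18, 0.09,
  0.045, 0.02; NO2: 0.12, 0.06, 0.03, 0.015; β_T = β_W = 0.08;
  β₀ = 0.32 targets a mean near 1.6 with a maximum near 9; λ capped at 9 as
  an overflow guard). A deterministic variant (counts = round λ) exists for
  exact-reproducibility tests. The Poisson log-linear link is the field's
  standard exposure–outcome mechanism; it exists to give validation a known
  structure to recover, not to claim the real data follow it.

Each variable draws from its own RNG stream spawned from the root seed, so
adding a variable never perturbs the others, and identical seed + config
gives bitwise-identical series.

Because covariates are standardized and centered inside the link, raising a
protective coefficient's magnitude strengthens the negative
temperature–count correlation but (by Jensen's inequality) slightly raises
the mean count; the generator makes no attempt to re-center β₀ under
coefficient overrides.

What the generator does **not** emulate: day-to-day autocorrelation of
counts beyond what the smooth covariates induce (counts are conditionally
independent), overdispersion, spatial heterogeneity of exposure, holidays
or weekday patterns, and measurement gaps. Passing tests therefore show
that the pipeline recovers a known exposure–outcome structure of realistic
magnitude and seasonality — not that the model's real-data accuracy is
reproduced.

## Problem sizes

The structure-recovery check uses 100 replicates of 730-day series
(two years, the study's span), which runs in seconds thanks to vectorized
inference; sweeps use 21×21 pollutant grids at the four temperature/wind
plateau corners; AUC correctness is checked on 200 random instances of
n ≤ 50 against literal pair enumeration.

## Known limitations

- Membership breakpoints other than the PM10 crossover are calibration
  choices constrained only by observed ranges; different placements change
  the numeric predictions (not the qualitative ordering enforced by the
  rule base).
- The output scale is anchored to a [0, 9] count domain; cities with higher
  admission volumes need a re-scaled output variable.
- Mamdani min–max inference is not globally monotone (see above); users who
  need strict monotonicity everywhere should evaluate at dispersion-plateau
  conditions or use the rule base with an additive aggregation, which this
  package deliberately does not implement.
- Pearson r on counts treats the outcome as continuous; with daily means
  near 1.6 the discreteness inflates p-value precision claims slightly.
  The validation mirrors standard practice in this literature rather than
  a count-likelihood comparison.
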