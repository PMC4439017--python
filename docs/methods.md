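# Methods

## Model and assumptions

The package treats a small aquatic ectotherm as thermally transparent:
its body temperature T_b equals the water temperature at its current
depth, because the heat capacity and conductivity of water equilibrate a
small body within minutes. Under this assumption the depth × time grid of
water temperatures in a column **is** the operative-temperature (T_e)
surface — what a randomly placed, non-regulating animal would experience
— and behavioral thermoregulation reduces to non-random depth choice.

Three standard indices quantify that choice against a preferred range
[T_p^low, T_p^high]:

* `d(t) = max(T_p^low − t, t − T_p^high, 0)` — deviation of a
  temperature from the range;
* d_e = deviation of the habitat (two conventions, below);
* d_b = deviation of T_b;
* E = d_e − d_b (difference form), or d_b/d_e (ratio form, undefined at
  d_e = 0). The ratio is reported exactly in the form d_b/d_e; note that
  part of the literature instead uses 1 − d_b/d_e, so ratio values are
  not comparable across sources without checking the formula. The
  difference form is the default everywhere.

Because shallow columns warm substantially between morning and late
afternoon, indices are computed per individual per clock hour
(10:00–17:00 by default) and only then aggregated.

## Conventions that matter

**d_e convention.** `deviation_of_mean` (default) deviates the
column-mean T_e from the range. `mean_of_deviations` averages the
per-depth deviations. The two differ whenever the column straddles the
range: by Jensen's inequality deviation-of-mean ≤ mean-of-deviations.
Only under mean-of-deviations does a depth-indifferent animal satisfy
E[d_b] = d_e, hence E[E] = 0 — so the thermoconformer null check uses
that convention, while headline summaries use deviation-of-mean. Output
metadata records which was used.

**T_p range.** Per-individual ranges are the 10th/90th percentiles of
temperatures selected in a cost-free thermal gradient (linear
interpolation between order statistics, rank (n−1)p/100). Individuals
inactive or out of the water for strictly more than 90 % of records are
excluded. The species-level range applied to all conspecifics is the mean
of individual lower bounds and the mean of individual upper bounds.

**Aggregation.** Species summaries default to grand means over
individual-hour records; averaging within individuals first is a config
option since the aggregation order is a reporting choice, not a modeling
one.

**Interpolation.** Profiles are bilinear in (depth, time); grid nodes are
returned exactly. A single interior missing logger reading is filled
linearly in time at its depth, a boundary gap takes the nearest value,
and two consecutive missing readings are an error rather than silently
imputed. Hourly analysis instants are evaluated by time interpolation of
the 30-min logger grid, not by averaging bracketing readings. Tanks
without loggers inherit a logger-equipped tank's profile through an
explicit tank map; the inter-tank consistency check (max cell-wise spread
across logger tanks, flagged above 1 °C) bounds the error of that
substitution.

## Inference

Group effects on indices use a one-way pseudo-F,
(SS_between/df_between)/(SS_within/df_within), with its null distribution
built by label permutation and the add-one p value
p = (1 + #{F* ≥ F_obs})/(1 + n_perm), n_perm = 9999 by default. Ties
count as extreme; a relative tolerance of 1e−9 absorbs last-ulp
differences that arise from summing identical values in permuted order.
Hourly records are pseudoreplicated within individuals, so the default
permutation unit is the individual (records are collapsed to individual
means before shuffling); record-level permutation must be requested
explicitly. Two-way designs test main effects by restricted permutation
within the other factor's levels and the interaction by Freedman–Lane
permutation of additive-model residuals. Degrees of freedom are reported
as computed from the analysis units actually used.

Confidence intervals are percentile bootstrap intervals (resampling with
replacement at the original n, 9999 replicates by default). Variance
explained by individual identity is the one-way share
100·SS_between/SS_total over records, flagged undefined when SS_total = 0.

The daytime trend model is the fixed-effects skeleton
`T = b0 + b1·hour + b2·hour² + species offset`, fitted by OLS on raw
decimal clock hours (uncentered; the convention is recorded here because
centering changes b0 and b1 but not the curvature). Random individual
intercepts/slopes and variance covariates of a full mixed model are out
of scope: OLS point estimates match the fixed-effects part, but standard
errors from repeated-measures data will be optimistic and are not
comparable to a mixed-model fit.

## Synthetic studies

The generator emulates the semi-natural design the analysis was built
for: a 45-cm column logged every 5 cm and every 30 min, a surface trend
quadratic in clock hour (default coefficients −17.076 + 4.912·t −
0.144·t², giving ≈17.6 °C at 10:00 rising to ≈24.8 °C at 17:00), linear
stratification of 0.08 °C/cm (surface warmer; 3.6 °C surface–bottom
spread), and i.i.d. Gaussian logger noise of 0.2 °C, chosen from the
0.5 °C logger resolution and consistent with inter-tank agreement within
1 °C. Agents are observed hourly 10:00–17:00 under two memoryless rules:
a *thermoregulator* that with probability `effort` (default 0.8) occupies
the depth minimizing deviation from its T_p range — ties broken to the
deepest such depth, since refuge from warm surface water lies below — and
otherwise, like the *conformer*, draws a uniformly random grid depth.
The canonical two-arm study is 30 regulators with a cool range
(16.5–19.0 °C) versus 26 conformers with a warm range (20.5–23.5 °C),
sizes matching the study design the pipeline mirrors. Gradient-trial
records are drawn normal around the range midpoint with the SD chosen so
the 10th/90th percentiles land on the range bounds, snapped to the
8–30 °C, 2 °C-step compartments; 15 individuals per species by default.

The ground-truth ledger stores the analytic expectation of E under the
mean-of-deviations convention, `effort · mean_h(mean_d d − min_d d)`,
computed on the realized column; for conformers it is exactly 0.

What the generator deliberately omits: temporal autocorrelation in depth
choice (no movement data exist to calibrate it), movement costs,
biophysical heat budgets, vertical profiles more structured than a linear
gradient, and missing or quantized logger readings. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated behavioral rules, not realism of newt movement.

## Numerical choices and problem sizes

* Percentiles: linear interpolation between order statistics (the common
  default), checked against a brute-force sort-and-interpolate oracle.
* Pseudo-F degenerate case: when a grouping leaves zero within-group
  variance with positive between-group variance, F is +inf rather than
  the sign-unstable ratio floating cancellation would produce.
* Bootstrap of a constant vector returns a degenerate interval equal to
  the point estimate.
* All resampling is seeded; the pipeline derives per-stage seeds from the
  run seed, and reruns on identical inputs are byte-identical.
* Test-suite simulation sizes (500 null datasets at 499 permutations for
  type-I error, 500 bootstrap replicates at 999 resamples for coverage,
  200 noisy trend replicates) were chosen so Monte-Carlo error is a few
  times smaller than the tolerance being checked.

## Known limitations

* The ratio form of E is reported as d_b/d_e verbatim; cross-study
  comparability of ratio values is the user's responsibility.
* The mean of a T_p sample can fall outside its own [P10, P90] band for
  strongly skewed samples; only lower ≤ upper is enforced.
* Observation hours must lie within the logger span; no extrapolation in
  time or depth is performed.
* The trend fit's standard errors ignore repeated measures (see above).
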