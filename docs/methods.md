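# Methods

## Outcome definition and anthropometric conventions

Decimal age is the calendar-day count between examination and birth divided
by 365.25; integer age is its floor, and all per-age analyses bin children
by integer age (the earliest measurement in the bin is the predictor when a
child has several). BMI = weight/height² (kg/m²), TMI = weight/height³
(kg/m³); the two differ exactly by a factor of height in metres, which the
test suite uses as a conservation check.

BMI is standardized by the LMS method: given skewness L, median M and
coefficient of variation S at a sex and age,

    z = ((x/M)^L − 1) / (L·S),   or  z = ln(x/M)/S  as |L| → 0,

with parameters linearly interpolated in age on the reference grid (the
bundled grid is half-yearly, so interpolation error is negligible). The
inverse transform `x = M(1 + L·S·z)^(1/L)` is used both to read reference
cutoffs (the BMI value at z = 1 or 2) and to construct synthetic cohorts.

Weight status uses the school-age convention on BMI z-scores: overweight
`1 < z ≤ 2`, obesity `z > 2`. Both boundaries are closed on the lower side
(z = 1 is normal, z = 2 is overweight) so the three categories partition the
line; the screening outcomes are **inclusive** overweight (`z > 1`,
overweight or obese — the clinically coherent target for an overweight
screen) and obesity (`z > 2`).

Eligibility requires at least 8 complete measurements and at least one
measurement with age in the closed window [16, 18]; the endpoint is the
*last* measurement inside that window, and its z-score defines the outcome.
Baseline is the chronologically first measurement; follow-up time is last
age minus first age. Reported percentages round half-up to one decimal, the
convention of printed clinical tables.

## ROC analysis and optimal cutoffs

Classification is always "positive if index ≥ threshold". The AUC of a
continuous marker is the Mann–Whitney probability that a random case
outranks a random control with ties half-weighted, computed from ranks; a
property test keeps it equal (to 1e-12) to the trapezoidal area under the
empirical ROC curve, an independently coded oracle.

Standard errors come from DeLong's placement-value estimator:
`var = S10/m + S01/n` where S10/S01 are sample variances of per-case and
per-control placements; the 95 % CI is a normal interval clipped to [0, 1]
(a logit-scale interval is available behind a flag). The paired test of
equality of two ROC curves on the same subjects uses the placement
covariances and a two-sided normal p-value; identical score vectors return
p = 1, and a zero-variance nonzero difference returns p = 0 with the z
statistic reported as infinite. Per-age comparison tables carry both raw
and Holm-adjusted p-values.

The "optimal" cutoff maximizes Youden's J = sensitivity + specificity − 1
over observed marker values. J ties are resolved first toward higher
sensitivity — a screening tool should prefer the lower false-negative
rate — then toward the lower threshold. Age–sex cells with fewer than
`min_cases` (default 10) cases or controls are omitted rather than reported
with unstable estimates.

## Fixed-cutoff AUC

A fixed threshold induces a binary score whose ROC has a single interior
point, so its area is exactly (sensitivity + specificity)/2. This definition
is applied uniformly to every cutoff system under comparison — cohort BMI,
cohort TMI, reference BMI, simplified TMI — making the systems comparable on
an identical footing; the DeLong machinery runs on the binary scores.
Reference-BMI thresholds are read off the LMS reference at the midpoint of
the integer-age year (age + 0.5).

## Cutoff–age regression and model selection

Five ordinary-least-squares forms describe how a cutoff varies with age t:
linear `y = a + bt`, quadratic `y = a + bt + ct²`, logarithmic
`y = a + b ln t`, log-linear `ln y = a + bt`, log-log `ln y = a + b ln t`.
R² for the log-response forms is computed on the transformed scale, so
cross-scale comparisons are approximate (flagged in the output). Selection
is by adjusted R², `1 − (1−R²)(n−1)/(n−p−1)` with p the number of slope
terms, with one practical-equivalence amendment: when the quadratic wins but
the nested linear form lies within 10⁻³ of it, the linear form is preferred.
Without this rule a spurious quadratic term would outrank a true linear
relationship in roughly a third of small-noise datasets (the extra term
gains adjusted R² whenever its t² > 1), while its gain is then an order of
magnitude below the tolerance. Non-nested forms are never demoted, because
genuinely equivalent descriptions exist (a parabola on ages 7–18 is also a
near-perfect power law) and the higher adjusted R² should stand.

The selection experiment in the test suite generates each form with small
noise (SD 0.02 in index units on the natural scale, 0.002 on the log scale)
at ages 7–18 and requires the generative form to win ≥ 90 % of 200
replicates. The log-log design uses a *decreasing* power law
(`exp(4.2 − 0.6 ln t)`): an increasing power law with exponent below 1 on
this short age range is nearly indistinguishable from a line, and no
selector could honour it.

## Merging into the simplified scheme

Per-age, per-sex TMI cutoffs are merged into one threshold per outcome and
age band (below 16 / 16 and over, the split configurable). For each
(outcome, band), candidate thresholds run from the floor to the ceiling of
the band's derived cutoffs in 0.1 kg/m³ steps. A candidate is scored by
dichotomizing TMI at every age in the band (sexes pooled, since the final
scheme is sex-free) and computing the fixed-cutoff AUC per age; candidates
keeping every per-age AUC ≥ 0.7 are feasible, and among them the scheme
takes the maximal mean AUC, ties broken by lower mean false-negative rate,
then by the lower threshold. If no candidate is feasible the best-effort
candidate is returned flagged infeasible — re-optimizing on the cohort
rather than averaging the per-age cutoffs, so the scheme is directly
accountable to the same outcome it will screen for.

The screening diagram renders the four thresholds as a decision table
(per band: [0, ow) low risk, [ow, ob) overweight risk, [ob, ∞) obesity
risk — lower bounds inclusive) plus a plain-text flowchart.

## The synthetic cohort generator

The generator is the package's test bed: real cohorts of this kind are not
public, so every downstream stage is exercised against simulated cohorts
with known ground truth.

**Latent structure.** Each child carries a stationary standard AR(1)
adiposity path u(age) with per-year autocorrelation `tracking_rho` (default
0.95); a gap of Δ years has coefficient rho^Δ, so rho = 1 gives a constant
path, rho = 0 independence, and corr(u(9), u(17)) = rho⁸ exactly. The
`innovation_sd` knob scales the stationarity-implied innovation SD
√(1−rho^2Δ); the default 1.0 keeps the unit-variance marginal. The BMI
z-score is an age-dependent affine map z(age) = μ(age) + σ(age)·u(age), and
BMI follows by the inverse LMS transform against the bundled reference — so
with zero measurement noise the generated BMI's z-score equals the latent
deviate identically, the generator's core invariant.

**Calibration.** μ and σ are anchored at baseline (age 9) and at the start
of the endpoint window (age 16, constant across [16, 18] so every endpoint
examination draws from one distribution), linear in between. Endpoint
anchors solve the two normal-tail equations for the target exclusive
prevalences — boys P(z>1) = 13.5 %, P(z>2) = 3.3 % giving
μ = −0.500, σ = 1.360; girls 6.4 %/1.1 % giving μ = −0.981, σ = 1.302.
Baseline anchors solve for the target baseline BMI mean (SD) of 18.5 (3.5)
in boys and 18.0 (3.2) in girls through the inverse LMS at age 9 by
Gauss–Hermite quadrature (boys μ = 0.551, σ = 1.272; girls μ = 0.410,
σ = 1.310). Latent deviates are winsorized at |z| = 4 before inversion: with
L ≈ −1.8 the inverse LMS is singular as L·S·z → −1 and the upper BMI tail
explodes; the cap keeps childhood BMI realistic and cannot affect either
prevalence. The baseline-to-endpoint drift in μ encodes a cohort heavier
than the reference in childhood but near it by late adolescence.

**Reference curves and anthropometry.** The bundled LMS reference is a
smooth synthetic stand-in for a BMI-for-age growth reference (half-year
grid, ages 5–19): a monotone median with a pubertal logistic rise, mildly
negative L and a small S. It is *not* a published reference table; any real
reference can be supplied as a standard LMS CSV. Heights come from a
monotone median-height table (modern East-Asian levels) plus one constant
per-child stature deviate (SD 5.7/5.3 cm); weight is back-computed from the
target BMI and true height, then height and weight each receive Gaussian
measurement noise (`measurement_noise_sd`, default 0.2 in cm and kg). The
BMI-median amplitudes and height levels were chosen together so the
simulated cohort reproduces the TMI-stability phenomenon — median TMI
varies by under ~1 kg/m³ across ages 7–18 while median BMI rises by more
than 3 kg/m² — despite the latent μ drift, which by itself would tilt TMI
downward.

**Schedules and dates.** Baseline age is truncated-normal 9.0 (SD 1.2) on
[6, 10.8]; the final examination age is truncated-normal 17.2 (SD 0.7)
inside [16, 18]; examinations are evenly spaced between them with at least
8 visits (spacing rescales slightly when the span is short). Examination
dates are a birth date plus the rounded day count, and the simulated age is
then *recomputed from the dates*, so the date-based age formula downstream
is exercised, not bypassed, and the zero-noise z-score identity survives the
1-day date rounding exactly. Each child consumes a counter-derived random
substream of the cohort seed, making per-child output independent of
generation order and cohorts byte-reproducible.

**What the generator does not emulate.** No secular trends, dropout,
puberty-timing or height-velocity modelling; no within-year seasonality; a
single AR(1) latent (no measurement-occasion adiposity shocks beyond the
noise term). Two consequences worth knowing: the simulated baseline mean
TMI (~13.5–14 kg/m³) exceeds the descriptive 12.4/11.9 values of the
emulated cohort, whose printed baseline BMI and TMI are mutually
inconsistent with any plausible age-9 height — BMI and the endpoint
prevalences were prioritized; and correctly-classified rates at young ages
(~70 % at age 8) sit below the emulated cohort's ~80–85 %, because the
calibrated latent shift places the merged threshold nearer the simulated
age-8 TMI median than it evidently was in the real data. Passing tests
demonstrate the pipeline's correctness on cohorts with this tracking
structure, not fidelity of any particular threshold value to a real
population.

## Numerical and design choices

- Quantiles use the median-unbiased (Hyndman–Fan type 8) definition — stable
  for small per-cell counts.
- The candidate grid in the merge step is rounded to 10 decimal places to
  keep 0.1-step arithmetic exact in binary floating point.
- Degenerate ROC cells (all values identical) return the shared value with
  J = 0 rather than erroring.
- Cohort CSVs are comma-separated UTF-8 with ISO-8601 dates and M/F sex
  codes (case-insensitive on read); duplicate (child, exam date) rows are
  structural errors, while implausible measurements (height outside
  30–230 cm, weight outside 5–250 kg) are excluded row-by-row and reported
  with line numbers.
- Problem sizes in the test suite: the heavier structural checks share one
  10,000-child cohort; the type-I-error study uses 1,000 replicates of 500
  subjects; the acceptance script simulates the full 17,815-child default
  once.
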