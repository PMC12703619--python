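# Methods

## Data model

All analyses consume a contiguous daily grid (`DailySeries`) of death
counts (total, male/female, ≥65/<65), meteorology (pressure hPa,
temperatures °C, wind m/s, relative humidity %), pollutant
concentrations (µg/m³; CO in mg/m³) and/or a composite AQI, plus
derived calendar covariates.  Dates are time-zone-naive local days;
day-of-week enters as six dummies contrasted against Monday; the
holiday list is user-supplied configuration (default: none).
Validation is strict: calendar gaps, negative counts, and stratum sums
that do not add to the total are hard errors naming the offending
dates.  Death counts are never imputed (they are the outcome);
meteorology and pollutant gaps may be linearly interpolated on an
explicit opt-in only.  Pressure values near 1000 are stored verbatim
and documented as hPa.

## AQI construction

Sub-indices interpolate linearly between the breakpoints of the
Chinese ambient-air-quality standard, shipped as a versioned CSV
resource (24-h segments for PM2.5, PM10, NO2, SO2, CO; ozone with
both 8-h-max — the default — and 1-h windows).  Sub-indices are
rounded **up** to integers per the standard's convention
(configurable); the composite AQI is the maximum sub-index, ties all
reported as primary pollutants (none reported at AQI ≤ 50).
Concentrations above a pollutant's top breakpoint return the top
index with an overflow flag rather than extrapolating, because the
scale is capped by definition.

## Natural cubic splines

`ns_basis` builds fixed-df regression splines by projecting a cubic
B-spline basis onto the null space of the two second-derivative
constraints at the boundary knots (QR of the constraint matrix);
points beyond the boundary are continued linearly via a first-order
Taylor expansion at the nearest boundary knot.  Interior knots default
to equally spaced quantiles of the data; boundary knots to the data
range.  No orthogonalization is applied — conditioning is handled by
column scaling inside the fitter — so coefficients remain directly
comparable to textbook constructions.  The unit tests verify the
column space against an independently coded truncated-power natural
basis.

## Cross-basis and relative risks

The cross-basis row for day t sums, over lags l = 0..L, the outer
product of the reference-centered exposure basis evaluated at the
exposure l days earlier with the lag basis evaluated at l.  Supported
bases: natural spline or plain linear in the exposure dimension;
natural spline over the integer lag grid (intercept retained, so
constant-in-lag effects are representable) or one indicator per lag.
When the lag-spline df reaches L+1 the parameterization is saturated
and falls back to indicators; L = 0 collapses to the exposure basis
alone.

Defaults: L = 7; 3 df in each dimension; reference = median AQI;
RRs reported at a configurable exposure (default the 90th AQI
percentile, "a high-AQI day") per 1-unit contrast.  Single-lag
log-RRs are linear contrasts of the cross-basis coefficient block;
cumulative log-RR at lag k is the sum of the single-lag contrasts
through k, so the cumulation identity holds to machine precision by
construction.  CIs are Wald intervals on the log scale using the
quadratic form of the contrast against the coefficient covariance.
Published lag tables of this kind cannot generally be reproduced
number-for-number (the underlying registries are not deposited, and
printed single-day and cumulative rows are not always mutually
consistent under any single contrast convention); this package
documents its own self-consistent convention instead.

## Poisson fitting

A single IRLS engine fits every model: log link, convergence at
relative deviance change < 1e-9 or 50 iterations (with step-halving
as an overshoot guard), coefficient covariance from the inverse
Fisher information.  Designs are assembled from named blocks; rank
deficiency is an error naming the collinear blocks, never silent
column dropping.  The first L rows (incomplete lag history) are
dropped, not zero-filled, and `n_used` is reported.  The default
variance model is pure Poisson; a quasi-Poisson flag rescales the
covariance by the Pearson dispersion for overdispersed series.  No
offset term is used (counts, not rates, are modelled).  AIC
(−2·loglik + 2p) supports a df scan across candidate designs fitted
to identical rows; ties break toward fewer coefficients.

Two model presets are provided because the two published equation
forms for this design differ: `gam_eq` (the default — humidity and
wind as 3-df spline terms) and `dlnm_eq` (pressure and wind as their
own 3×3 cross-bases).  `gam_eq` is the default because its confounder
terms are fully specified, whereas confounder cross-bases carry an
arbitrary internal reference.  The time trend uses 7 df per year of
data.  Subgroup models refit all terms per stratum.

## Interaction analysis

Exposures are dichotomized — AQI at a policy threshold (default 100,
the national good/polluted boundary), meteorology at the turning
point (argmin) of its overall exposure-response curve, falling back
to the median — and the four-parameter model
log μ = α + β₁E₁ + β₂E₂ + γE₁E₂ is fitted.  IRR = exp(γ) with a Wald
CI; RERI and AP CIs use the delta method on (β₁, β₂, γ) with the
fitted covariance (the gradient of AP follows from
AP = 1 − (RR10 + RR01 − 1)/RR11).  A seeded day-resampling bootstrap
(default 1000 draws) is available as a sensitivity check.  The AP
denominator is RR11 throughout; with a Poisson log link the
doubly-exposed relative risk plays the role an odds ratio plays in
case-control formulations, and AP·RR11 = RERI is asserted in tests.
Any empty exposure cell refuses estimation with an error naming the
cell; sparse polluted cells (< 30 days) trigger a warning suggesting
a lower threshold, since clean-air series may have only a dozen days
above 100.  Verdicts: synergistic if the RERI CI is entirely
positive, antagonistic if entirely negative, otherwise none.
Confounders are excluded from the default interaction model
(matching the printed two-way specification); an adjusted variant
adding trend + DOW is available for sensitivity.

## Synthetic-data generator

The generator emulates a seven-year (n = 2557 days) clean-air
subtropical city.  Meteorology: temperature as an annual cosine
(coldest mid-January) plus AR(1) noise; humidity Beta-distributed
around 76.3%; wind log-normal with median 2.0 m/s (mean ≈ 2.17);
pressure winter-high around 1000.7 hPa.  Pollutants: seasonal base
levels at published-median scale (winter-peaking except ozone, which
peaks in early autumn), multiplied by a dispersion factor decreasing
in wind speed and mildly increasing in humidity, times AR(1)
log-normal noise, floored at small observed minima.  The composite
AQI is then recomputed through the package's own breakpoint
interpolation.  The pollutant bases and noise scales were calibrated
once so the default AQI distribution has median ≈ 44, mean ≈ 46 and
range within [10, 200], with category frequencies (≈ 65% excellent,
≈ 34% good, < 1% polluted) matching a clean-air city.

Mortality: log μ_t = baseline (log 25.8) + seasonal winter excess
(amplitude 0.08) + small day-of-week offsets + holiday effect +
Σ_l slope·w_l·max(AQI_{t−l} − threshold, 0), with the hinge at AQI 80
by default — echoing the observation that risk rises once AQI
exceeds 80 — slope 0.0015 per unit and lag weights (0.5, 0.3, 0.2)
over lags 0–2.  An optional γ·E₁E₂ term injects a multiplicative
AQI × meteorology interaction using median splits.  Sex and age
strata are binomial thinnings of the total (male share 0.533; ≥65
share 0.80, a typical fraction for cardiovascular mortality), which
keeps the additive invariants exact; stratum-specific exposure
effects tilt the thinning probability.  All randomness flows from a
single seeded generator; replicate k uses seed + k.

What the generator does **not** emulate: spatial/station structure,
pandemic-period regime shifts, measurement error in the pollutant
record, and real-world overdispersion of death counts (counts are
exactly Poisson).  Passing recovery tests therefore demonstrates the
estimators are correct under the stated model, not that the model
captures every feature of registry data.

## Validation design and problem sizes

Correctness is property-based, since the motivating registry is not
public: spline bases against a truncated-power oracle; the IRLS
engine against a from-scratch Newton–Raphson maximizer (and
statsmodels as a second cross-check in unit tests); the cross-basis
against explicit loop construction and direct lagged regression; the
cumulation identity to 1e-10; interaction arithmetic against closed
forms.  Monte-Carlo checks use n = 2557 days with 200 replicates for
lag-surface recovery and null coverage (linear × indicator fit, so
the estimand is exactly parameterized), 1000 saturated 2×2 tables
for type-I error, and 500 replicates for interaction recovery.  The
interaction-recovery harness splits AQI at the series median rather
than at 100: a significance verdict is the target of that
experiment, and the handful of days above 100 in a clean-air series
carries too little information for a stable γ estimate — the
package instead surfaces that sparsity to users via the cell-count
warning.

## Known limitations

* Fixed-df regression splines only; no penalized smoothing.
* No negative-binomial or autocorrelation-robust alternatives; the
  quasi-Poisson flag is the only overdispersion control.
* Attributable fractions and multi-pollutant lag models are out of
  scope.
* The RR-evaluation exposure and reference are conventions; absolute
  RR magnitudes depend on them and should be reported alongside.
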