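# Methods

## Scope and data model

The package analyses isothermal degradation studies: per storage
temperature, a time series of analyte concentrations (means over
replicates, mg/100 mL) starting at day 0. Time stays in days and
temperature in °C at every interface; conversion to Kelvin (exactly
T + 273.15) happens only inside the secondary models. Replicates are
averaged into per-time means before fitting, with the per-cell SD kept as
`replicate_sd`; the fits themselves operate on means. Whether replicate-level
fitting would be preferable is an open modelling question — with the small,
homoscedastic replicate spread the generator assumes, the two give the same
point estimates, so the simpler convention was chosen.

## Primary models

Zero- and first-order fits are ordinary least squares of C and ln C on t;
the rate constants are the negated slopes, R² the squared Pearson
correlation, and the fitted intercept is reported as the model's C0.

The Weibull fit works on retention with C0 **fixed** to the measured day-0
value, because the model form Y(t) = exp(−b·tⁿ) forces Y(0) = 1; a free-C0
variant is deliberately out of scope. The sum of squared retention
residuals over the t > 0 points is minimized by bounded
trust-region-reflective least squares (`scipy.optimize.least_squares`,
cost tolerance 1e-10) with b ∈ [1e-8, 10] day⁻ⁿ and n ∈ [0.01, 5]. The
start point is n = 1 and b = the first-order rate from a log-linear
pre-fit (floored at 1e-4); if that local solve fails, a log-spaced
12 × 10 (b, n) grid is scanned and the best cell refined. Because the
model with n = 1 is exactly first-order decay, the converged Weibull SSE
can never exceed the best exponential fit's SSE on the same retention
points — this nesting is asserted in the test suite over random series.

Goodness of fit is uniform across models: MSE = SSE / (number of fitted
points) with no degrees-of-freedom correction, RMSE = √MSE, and for
nonlinear fits R² = 1 − SSE/SST with SST about the mean response. The
day-0 point has a structurally zero residual in the Weibull
parameterization, so it is excluded from both SSE and SST; including it
would inflate R² through a residual the model cannot miss. (For series
that are not printed anywhere, either convention is defensible; this one
is documented rather than inferred.)

Model selection takes the highest R²; ties within 1e-4 go to the model
with fewer kinetic parameters, so noiseless exponential data select
first-order rather than the Weibull fit that shadows it. Series whose
overall concentration trend increases are still fitted but flagged
`non_degrading` — downstream shelf-life numbers are meaningless there and
the flag propagates into the report.

## Secondary models

The Arrhenius fit is OLS of ln q on 1/(T + 273.15) with
R = 8.314 J/(mol·K). Orientation matters only for the sign convention:
for a rate-like quantity (the Weibull scale b) Ea = −slope·R; for a shelf
life, which shrinks with temperature, Ea = +slope·R. The slope's standard
error (residual variance / Sxx, dof = n − 2) is scaled by R and reported;
with two points it is undefined and reported as absent. With the usual
three-temperature design every secondary fit has one residual degree of
freedom, so `n_points` rides along and the standard errors should be read
as descriptive, not inferential.

The log-logistic curve b(T) = ln(1 + exp(k3(T − Tc))) is evaluated in the
softplus form max(x, 0) + log1p(exp(−|x|)), finite for any argument. The
fit is bounded least squares over k3 ∈ [1e-4, 5] (1/°C) and
Tc ∈ [−50, 300] °C from an 8 × 9 multi-start grid, keeping the best
converged solution. On the reference b(T) triples this lands exactly on
the published (k3, Tc) for both matrices, i.e. the reference values are
the global optimum to the printed precision. Both secondary models are
reported; neither feeds the shelf-life extrapolation, which regresses t80
directly.

## Shelf life

t_f = ((−ln f)/b)^(1/n), with f defaulting to 0.80 (the conventional
nutritional-acceptability threshold) but exposed as a parameter. Rounding
to whole days is half-away-from-zero, which reproduces all six reference
integers (18.78→19, 8.39→8, 2.90→3, 31.15→31, 17.44→17, 8.84→9); the
unrounded values are what enters the ln t vs 1/T regression — rounding
first visibly shifts the slope (≈9326 instead of 9420 for the camu camu
reference set). Predictions at requested temperatures evaluate the fitted
line; anything outside the fitted temperature span is flagged as an
extrapolation and should be read as an indicative estimate, since it rides
on a two-parameter line through (typically) three points.

## Synthetic studies

The generator emulates the reference accelerated design: 35 °C sampled
every 3 days to day 21, 45 °C every 2 days to day 14, 55 °C daily to day
7 (eight points each including day 0), triplicate measurements, with
Weibull-shaped mean decay at the reference (b, n) per temperature and the
reference initial concentrations (1090.17 mg/100 mL camu camu, 43.47
naranjilla). Noise defaults to additive on the retention scale with
sd 0.005, consistent with the small replicate SDs the reference matrices
show relative to their means; additive-concentration and proportional
options, plus a heteroscedastic variant whose sd grows with the degraded
fraction, cover alternative error assumptions — no single noise model is
canonical for this kind of data. Concentrations are truncated at
1e-6·C0 to preserve positivity; at default noise the truncation
essentially never binds. Seeds are mandatory and all randomness flows
through one `numpy.random.default_rng(seed)`, so identical configs are
bit-identical.

What passing simulation tests shows: the estimator recovers the
parameters it assumes, at the noise level it assumes. What it does not
show: robustness to instrument drift, autocorrelated errors, batch
effects, or non-isothermal storage, none of which the generator produces.

The recovery harness simulates many studies, runs the full pipeline on
each, and reports per-temperature relative errors of (b, n, t80) and the
spread of fitted Ea. A practical sensitivity worth knowing: because
t_f ∝ b^(−1/n), a shape parameter around 0.23 (the hotter reference
conditions) raises retention-scale noise to roughly the 4th power in the
shelf-life estimate — sd-0.01 noise yields ~10% median error in b but can
move individual t80 estimates by over 10%. Single-study Ea estimates from
three temperatures are similarly wide (±30% excursions at sd 0.01); their
median across replicate studies is unbiased.

## Analytical utilities

Titratable acidity uses V·N·0.06404·100/V_sample with the 0.06404 g/meq
milliequivalent weight of citric acid. The formula is sometimes printed
with the equivalent weight 64.04 g/eq and V in mL, which lands 1000× off
the conventional g/100 mL scale; the milliequivalent reading is the one
that reproduces reported acidity magnitudes (e.g. ≈0.52 g/100 mL for
fresh camu camu juice) and is what the implementation uses.

Calibration is OLS of peak area on standard concentration; LOD/LOQ come
from supplied baseline noise as 3σ/slope and 10σ/slope when available,
else from the calibration residual SD with the conventional 3.3/10
factors — both routes exist because published limits rarely state which
was used. Quantification inverts the line, applies the dilution factor,
and converts mg/L to mg/100 mL; areas outside the calibrated range and
non-positive back-calculations warn rather than fail.

The Pearson screen is the standard product-moment correlation with the
usual qualitative labels (|r| ≥ 0.70 strong, 0.40–0.69 moderate, < 0.40
weak). It is validated on synthetic co-generated series only; no
reference correlation values are asserted because the underlying raw
series are not published.

## Problem sizes and determinism

The test suite's stochastic checks use 100 simulated studies at sd 0.01
for the recovery check and 50 random series for the nesting property;
the full suite runs in about a minute on one CPU. All stochastic tests
fix their seeds; the pipeline itself is deterministic, and report
rendering regenerates byte-identical output for identical inputs.

## Known limitations

- Three-temperature designs leave one degree of freedom in every
  secondary fit; the package reports, not tests, those fits.
- Shelf-life extrapolation assumes the Arrhenius line holds 30 °C below
  the coldest measured condition — a modelling assumption, not a finding.
- Only mean-curve fitting is implemented; weighted or replicate-level
  fits, fitted-C0 Weibull variants, nth-order kinetics and WLF/Eyring
  secondary models are out of scope.
- Microbiological and sensory shelf life are different quantities;
  t_f here is purely a nutrient-retention threshold.
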