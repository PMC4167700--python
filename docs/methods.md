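# Methods

## The measurement problem

Automatic QT-interval measurement differs systematically between ECG
machine manufacturers: algorithms disagree on where the T wave ends (mean
of 12 leads vs global earliest-onset/latest-offset) and on how RR is
averaged. When cohorts recorded on different machines are pooled — in
GWAS of repolarization or drug-safety QT screening — the device offset
(≈ 10 ms after optimal rate correction, roughly twice the sex effect)
confounds any covariate of interest. The package estimates that offset,
and fits and validates the heart-rate corrections it depends on.

## Outlier gate

Model: within a stratum, (x, y) = (ln RR, ln QT) (or the raw pair) is
bivariate normal. The gate fits the five moments (two means, two SDs with
the n−1 denominator, Pearson correlation) and excludes points whose
squared Mahalanobis distance

    d² = (zx² − 2·rho·zx·zy + zy²) / (1 − rho²),  z = (v − mean)/sd

exceeds the coverage-p contour. Since d² of a bivariate Gaussian is
chi-square with 2 df, the cutoff is exact and closed-form:
t = −2·ln(1 − p); numerically identical to `chi2.ppf(p, 2)` (tested).
Using a 1-df quantile here would be wrong (empirical coverage ≈ 99.55%
instead of 99.9% at p = 0.999), which the coverage tests would catch.

Choices the source analysis leaves open, fixed here:

* **Per-stratum fitting** (manufacturer × sex) by default, because
  exclusion rates are reported per stratum; a pooled option exists.
* **Single pass**: the gate is fitted once and never refitted after
  exclusion. A consequence is that re-gating an already-gated table can
  exclude a few additional boundary points (the refitted SDs shrink
  slightly); the pipeline idempotence test therefore asserts fits agree
  to ~1e-3, not bit-exactly.
* **Natural logarithm** throughout. Classification is log-base-invariant
  (only affine rescalings are involved); fitted slopes are not, so the
  base must be declared.
* Classification is invariant under affine rescaling of either axis, so
  gating in seconds or milliseconds is equivalent (tested).

Degenerate inputs (n < 3, zero variance, |rho| = 1) raise errors naming
the stratum. Exactly collinear data — e.g. a zero-noise power-law cohort
gated on the log scale — are degenerate by construction; end-to-end tests
of the zero-noise limit therefore use a vanishingly small residual SD
(1e-8 … 1e-6) rather than exactly zero when the gate is in the loop.

## Heart-rate correction

Two regression scales, fitted per manufacturer with sexes pooled:

* log: ln QT = d + c·ln RR + error → power correction QTc = QT·RR^(−c);
* raw: QT = b + a·RR + error → linear correction QTc = QT + a·(1 − RR).

The intercept is discarded by anchoring at RR = 1 s, so QTc = QT at
60 bpm for every method (identity tested to 1e-12). Named formulas are
the power/linear families at fixed parameters: Bazett 1/2, Fridericia 1/3
(the standard exponent; adopted explicitly since only the method name is
given in the source), Framingham 0.154, ECAPS12 1/7.

Validation regresses ln QTc on ln RR; the slope beta is 0 for a perfect
correction, and on noise-free power-law data with exponent alpha a
power-gamma correction leaves exactly beta = alpha − gamma (property
tested on a grid). Validation is standardized on the log scale for all
methods, with a raw-scale option; the two differ only in how residual
curvature is weighted. 95% CIs use the t distribution with n−2 df;
p-values are two-sided; R² is the squared Pearson correlation. Fitting is
ordinary least squares via statsmodels, cross-checked against explicit
normal equations in the tests.

## Device-effect model

Pooled-manufacturer OLS: QT ~ RR + sex + age + manufacturer, with
indicator coding male = 1 / female = 0 and second manufacturer = 1 (label
order taken from first appearance or given explicitly). An equivalent
1/2 sex coding only shifts the intercept. On the raw scale the fit is
performed in milliseconds so additive coefficients read in ms while the
RR slope stays unitless; log-scale coefficients are scale-invariant.

A log-scale manufacturer coefficient c is expressed in milliseconds by
the multiplicative back-transform baseline·(e^c − 1); the linear
approximation baseline·c differs by about 0.15 ms at c = 0.0275 and a
400 ms baseline, an ambiguity worth noting when comparing to rounded
published values.

The age-adjusted RR device offset (RR ~ age + manufacturer, per sex) is
reported both in ms and as a percentage. Percentages require a
denominator, which the source analysis does not define; here it is
explicitly the model's predicted RR for the first manufacturer at the
stratum's mean age, stored alongside the percentage.

Between-group tests: Student (pooled-variance) t test by default, as in
the source analysis, with Welch as a flag. Fisher's exact test uses the
two-sided probability-mass convention (sum over tables whose
hypergeometric probability does not exceed the observed), matching R's
`fisher.test`; two-sided Fisher conventions differ between packages, so
this is stated rather than assumed.

## Synthetic cohort generator

The generator emulates the *structure the analysis assumes*, calibrated
to the published stratified table (four manufacturer × sex strata with
n = 8,631 / 1,898 / 42,673 / 30,081; RR 859.7±132.8 … 947.6±151.2 ms;
ages 46.1±9.2 … 53.6±16.5 y) and to the printed regression coefficients:

* RR is lognormal, moment-matched per stratum, so ln RR is exactly
  Gaussian — consistent with the observation that the log-transformed
  variables are closer to normal. Raw mode keeps lognormal RR and only
  changes the QT link.
* Age is Gaussian truncated at 20 years (study inclusion). The small
  truncation shift (< 2% at these moments) is handled analytically when
  calibrating.
* QT: ln QT (log mode) or QT (raw mode) = intercept + slope·x + gender
  effect·1[male] + age effect·age + manufacturer effect·1[second] +
  Gaussian noise. Default effects are the published multivariate
  estimates (log: −0.0123, 0.000686/y, 0.0275; raw: −5.154 ms,
  0.276 ms/y, 10.610 ms); slopes 0.347 (log), 0.156/0.152/0.153 (raw
  FD/NK/combined).
* **Intercept**: a single baseline fitted by n-weighted least squares so
  stratum mean QT matches the published table as closely as the
  coefficient structure allows (the published moments and coefficients
  are mutually consistent to ≈ 2 ms, so stratum means land within
  ~0.5%). A single intercept — rather than per-stratum pinning — keeps
  the generating coefficients exactly recoverable by the multivariate
  fit, which is what the recovery tests measure.
* **Noise**: specified either as a residual SD or as a target R² of the
  pooled simple QT-on-RR regression (the quantity the source reports:
  0.609/0.612 log, 0.608/0.607 raw; combined presets use the n-weighted
  averages 0.611 and 0.607 since no combined value is printed). The
  residual SD is solved in closed form from the stratum-mixture moments:
  R² = Cov(x, y*)² / (Var x·(Var y* + σ²)) with y* the deterministic
  part; this reduces to σ = |slope|·SD(x)·sqrt(1/R² − 1) when covariate
  effects are zero (tested), and accounts for the between-stratum
  covariate variance otherwise. Targets above the attainable maximum
  raise "impossible calibration".
* One RNG stream, fixed stratum order (FD-male, FD-female, NK-male,
  NK-female): identical (params, seed) give byte-identical tables.
* Homoskedastic residuals and no age→RR effect by default (coefficient
  configurable): nothing else is stated about the real data.

What passing recovery tests do **not** show about real data: the
generator has no heteroskedasticity, no measurement-algorithm mechanism
(the device effect is a calibrated additive offset), no premature beats,
and Gaussian tails exactly — so the 99.9% gate excludes ≈ 0.1% here,
whereas the real extracts showed 0.4–0.6% outliers with heavier tails.

Because the pooled simple regression also absorbs between-stratum sex/age
structure, recovered simple slopes carry a small, analytically expected
bias (≈ ±0.003 at the default calibrations), well inside the sampling
spread at the problem sizes used.

## Problem sizes and numerics

Recovery checks run at n = 10,000 (slopes), 50,000 (multivariate device
coefficient) and 70,000 (R² calibration), and gate coverage at 10⁶
simulated points — sizes at which sampling SES are a few per mille and
each check runs in seconds. Zero-noise identities are asserted at 1e-10
… 1e-12; OLS is cross-checked against normal equations at 1e-10;
Mahalanobis distances against explicit covariance inversion at 1e-10.
Report rendering rounds once (round-half-even) to one decimal in ms and
reuses the rounded values across text/TSV/JSON so formats agree exactly.

## Known limitations

* The generator's manufacturer effect is phenomenological; it cannot say
  *why* devices disagree, only reproduce the magnitude of disagreement.
* Single-record strata render with SD 0.0 (with a warning); empty strata
  render as n = 0 rows.
* Re-gating gated data is only approximately idempotent (see above).
* Each row is an independent subject; no repeated measures or
  mixed-effects structure.
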