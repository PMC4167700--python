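# qtcohort

Tools for comparing automatic QT/QTc interval measurements between ECG
machine manufacturers, built around three pieces of statistical machinery:

1. **Ellipse outlier gating.** Automatic T-wave-end detection occasionally
   fails; failures show up as extreme (QT, RR) pairs. Points are excluded
   when they fall outside the probability contour of a bivariate normal —
   fitted by plain sample moments on either (ln QT, ln RR) or raw axes —
   that encloses 99.9% of the density. For 2 degrees of freedom the squared
   Mahalanobis cutoff is closed-form: `t = -2 ln(1 - p)` (13.8155 at
   p = 0.999).

2. **Heart-rate correction fitting.** QT shortens as heart rate rises, so
   QT is reported corrected to RR = 1 s (60 bpm). Fitting ln QT on ln RR
   gives a power-law correction `QTc = QT · RR^(-alpha)`; fitting raw QT on
   raw RR gives a linear one `QTc = QT + s · (1 - RR)`. Both are anchored so
   QTc = QT at RR = 1 exactly. Published formulas (Bazett alpha = 1/2,
   Fridericia alpha = 1/3, Framingham s = 0.154, ECAPS12 s = 1/7) are special
   cases. A correction is validated by the residual slope beta of ln QTc on
   ln RR: beta = 0 means rate dependence is fully removed, and on power-law
   data beta = alpha_true − alpha_used (so Bazett over-corrects Japanese
   resting ECGs, beta ≈ −0.15).

3. **Device-effect estimation.** With two manufacturers pooled, the model
   `QT ~ RR + sex + age + manufacturer` (log or raw scale, indicator coding:
   male = 1, second manufacturer = 1) isolates the measurement offset
   attributable to the machine's algorithm. A log-scale coefficient c maps
   to milliseconds via the back-transform `baseline · (e^c − 1)`.

Because the original manufacturer extracts are proprietary, the package
includes a calibrated synthetic cohort generator (`qtcohort.simulate`)
reproducing the published stratified moments and regression structure of
two large Japanese resting-ECG datasets (Fukuda Denshi, n = 10,529; Nihon
Kohden, n = 72,754), so every stage is testable by parameter recovery.

## Worked example

```python
import qtcohort as qc

# simulate a Nihon-Kohden-calibrated cohort (~22k ECGs) and gate outliers
params = qc.default_params("nihon_log").scaled(0.3)
table = qc.generate_cohort(params, seed=1)
inliers, summary = qc.apply_gate(table, scale="log", coverage=0.999)
print(round(summary.strata[0].outlier_pct, 2))   # 0.13  (% excluded, male stratum)

fit = qc.fit_log_correction(inliers)
print(round(fit.slope, 3), round(fit.r_squared, 3))   # 0.343 0.612

model = qc.build_correction(fit)       # QTc = QT * RR^-0.343
beta = qc.residual_slope(inliers, model).slope
print(round(beta, 6))                  # -0.0  (rate dependence removed)

bazett = qc.residual_slope(inliers, qc.CorrectionModel("bazett")).slope
print(round(bazett, 3))                # -0.157  (Bazett over-corrects)
```

The fitted slope 0.343 recovers the generating exponent 0.347 to sampling
error; the near-zero residual beta certifies the fitted correction, while
Bazett's exponent 0.5 leaves a residual slope of about 0.347 − 0.5.

The same analysis runs from the shell:

```bash
qtcohort simulate --preset combined_log --n-scale 0.1 --seed 1 --out cohort.csv
qtcohort run --in cohort.csv --out-dir results/
qtcohort report --preset combined_log --n-scale 0.1 --seed 1 --format text
```

`run` writes a stratified Table-1-style report (text/TSV/JSON) with per
stratum mean ± SD of QT, RR and every QTc method, per-manufacturer fitted
corrections, residual-beta validation, Fisher outlier-rate tests and the
multivariate device model.

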