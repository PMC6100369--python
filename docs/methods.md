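# Methods

This note documents the models and procedures nirquant implements,
the defaults it chooses where the underlying methods leave choices
open, and what its validation on synthetic data does and does not
demonstrate.

## Reference method: ELSD power-law quantitation

Evaporative light scattering detection is not linear in mass: the
response follows A ≈ k·mˢ with s typically between 1 and 2, so
calibration is performed on log-log axes. `fit_loglog` regresses
log₁₀(area) on log₁₀(injected mass, mg) for a standard dilution
series and reports slope, intercept, Pearson r and the mass range.

Sample quantitation anchors on the same exponent via
`fit_power_from_table`: OLS of log₁₀(area) on log₁₀(content) across a
set of (area, content) determinations, inverted to
content = c·area^(1/s) with c = 10^(−intercept/s). The package embeds
a 150-sample determination table (`table2_fixture`); across it the
fitted exponent is 1.5608 with r > 0.9999, i.e. the whole table is
mutually consistent with a single power law, and leave-one-out
refits reproduce every tabulated content within ±0.0005 % w/w (140 of
150 exactly at four decimals).

Two deliberate interpretation choices:

* The printed standard curve's "y" and "x" are read as log₁₀(peak
  area) and log₁₀(injected mass). This is the only reading consistent
  with ELSD practice and with the determination table's pairwise
  area/content ratios.
* The absolute dimensional chain (mass per injection → extract →
  % w/w via the 1 g / 50 mL / 20 μL workup) is exposed as
  `content_from_mass_chain` for transparency but is **not** used for
  quantitation: its absolute scale disagrees with the determination
  table by a constant factor of roughly 50, so the power law fitted
  to (area, content) pairs — which the table obeys exactly — is the
  operative calibration.

Contents are formatted at 4 decimals, rounded half-away-from-zero,
matching the convention of printed determination tables.

## Spectral pretreatment

All operators preserve the wavenumber axis and sample order.

* **SNV** standardizes each spectrum to mean 0, sample (n−1) sd 1.
* **MSC** regresses each spectrum on a reference (the mean
  calibration spectrum) by OLS, x = a + b·r, and returns (x − a)/b.
  The reference is fitted once on calibration data and reused for all
  later data — never re-estimated on prediction sets.
* **FD/SD** are central finite differences scaled by the grid
  spacing, with one-sided second-order stencils at the ends so output
  length equals input length.
* **SG** is Savitzky–Golay least-squares polynomial
  smoothing/differentiation (scipy implementation), derivative scaled
  by Δν^deriv, edges evaluated from a polynomial fitted to the
  terminal window. Defaults: window 11 points, polyorder 3.
* **Norris** is the gap–segment derivative: segment means S_i over
  `segment` points, D1_i = (S_{i+g} − S_{i−g})/(2gΔν),
  D2_i = (S_{i+g} − 2S_i + S_{i−g})/(gΔν)². Segments are centred, so
  `segment` must be odd; points whose segments fall off the axis copy
  the nearest valid value. Defaults: segment 5, gap 5.

Composite labels follow the screening-table vocabulary. "MSC + SD +
SG" executes MSC first, then a *single* SG second-derivative step —
the derivative is folded into the SG filter rather than applying a
finite difference and then smoothing, which is the standard coupling
and avoids double differentiation. The SG/Norris parameters above are
common chemometric defaults; the commercial packages used in routine
practice do not disclose theirs, and none of the package's
conclusions depend on matching them.

Spectra cut to multiple windows have a spacing jump at each window
junction. Derivative-type operators are applied independently per
maximal uniform segment, so no derivative ever spans a gap.

## PLS1 calibration

NIPALS with a single response, centring only (no autoscaling of
spectral columns — standard for spectra). Per factor: weight
w = Xᵀy/‖Xᵀy‖, score t = Xw, loadings p = Xᵀt/tᵀt, q = yᵀt/tᵀt,
deflation X ← X − tpᵀ, y ← y − qt. The regression vector is
b = W(PᵀW)⁻¹q; PᵀW is unit upper triangular, so the solve is
well-posed. For one response no within-factor iteration is needed and
the fit is exactly deterministic. Extraction stops early if the
residual response energy falls below 10⁻¹² of its initial value
(numerical degeneracy guard); the model records the factors actually
extracted.

**Cross-validation** is leave-one-out: deterministic (no split seed),
and the default of the commercial software this field uses. Each fold
refits from scratch including re-centring; there are no shortcut
formulas, and the implementation is tested against a brute-force
refit oracle. PRESS(a) = Σ(ŷ₍ᵢ₎ − yᵢ)², RMSECV = √(PRESS/n). One
NIPALS pass per held-out sample yields predictions at every factor
count, so the PRESS curve costs n fits, not n·a_max.

**Factor selection**: smallest a with RMSECV ≤ 1.02 × min(RMSECV)
(2% parsimony rule, configurable). The sources that motivate this
package state only that the factor count is determined from PRESS and
RMSECV; the explicit rule is this package's documented choice. a_max
defaults to 10.

## Metrics and model selection

* R² is reported twice: on fitted calibration predictions (`r2`) and
  on cross-validated predictions (`r2_cv` = 1 − PRESS/SStot).
  Screening tables that pair a determination coefficient with RMSECV
  are compared against the cross-validated variant.
* RMSEC/RMSEP are root-mean-square errors on calibration/validation
  predictions; bias is the mean validation residual.
* RPD = sd(y_validation; n−1)/RMSEP, the Abstract-style definition
  using RMSEP as the standard error of prediction; RPD·RMSEP =
  sd(y_val) identically. Perfect prediction reports RPD = +inf.
* Grid search evaluates every pretreatment × window-set cell
  independently (cell failures are recorded, not fatal), ranks by
  ascending RMSECV with ties broken by descending cross-validated R².
* The calibration/validation split is seeded uniform sampling without
  replacement; a validation content outside the calibration content
  range triggers a warning (extrapolation), not an error.
* `boxcar_select` aims a near-uniform ("boxcar") reference-value
  histogram: equal-width bins over the content range, picks spread as
  evenly as availability allows (greedy top-up of the least-filled
  bin, ties toward the fullest), seeded-random choice within bins. It
  is a documented stand-in with the same stated goal as proprietary
  neighborhood-distance selection tools, not a replication of them.

One source contradiction is worth recording: the study design this
package generalizes describes 150 spectra split 120 calibration / 30
validation, but elsewhere speaks of 150 datasets "belonging to the
verification set". The package follows the 120/30 reading. Published
RMSEP values in the window-screening table (0.1064–0.226 % w/w) also
sit on a scale inconsistent with the corresponding RMSECV values
(0.019–0.059 % w/w); they are treated as printed, without
reinterpretation, and no package result depends on them.

## Synthetic data generator

The generator provides ground truth for end-to-end tests; it
emulates the *statistical structure* a PLS calibration assumes, not
diffuse-reflectance physics (no Kubelka–Munk, no instrument line
shape, no claim of spectroscopic fidelity for the analyte beyond its
band positions).

Per sample: clean = y·analyte + Σ cⱼ·interferentⱼ + (a + b·ν);
observed = m·clean + offset + ε, with m ~ N(1, 0.05),
offset ~ N(0, 0.01), cⱼ lognormal around 1, and ε Gaussian with sd
10⁻⁴ absorbance, inflated ×10 on 4000–4200 cm⁻¹ (the fibre-absorption
region real calibrations exclude as too noisy; the generated data
reproduce that ≥5× noise contrast).

Design choices, fixed once:

* Axis 4000–10000 cm⁻¹ at 4 cm⁻¹ spacing (1501 points) — desk-scale;
  the instrument's native 0.5 cm⁻¹ resolution is configurable but
  eightfold larger matrices buy nothing for validation.
* Analyte bands at 4250, 4357, 4762, 5168, 5776, 6848 and 8248 cm⁻¹
  (the C–H/O–H/C=O combination and overtone assignments of a
  cycloartane glycoside), Gaussian, σ = 60 cm⁻¹ in the combination
  region and 120 cm⁻¹ for overtones, amplitudes scaled so a 0.3 % w/w
  content contributes ~0.05 absorbance at 5168 cm⁻¹.
* Three matrix components (honey-sugar-like, cellulose-like,
  water-like) with broad bands deliberately overlapping 5168 and
  6848 cm⁻¹, at amplitudes giving ~1 AU total absorbance — typical of
  log(1/R) spectra of powdered plant material, and keeping the minor
  analyte a small fraction of total signal as it is in reality.
* Matrix compositional variation: 2% relative sd per component
  (lognormal). Batches here are the same herb under the same
  processing, whose major constituents vary far less than the minor
  analyte (which spans a fourfold content range); 2% keeps the
  matrix realistic while leaving scatter, baseline and noise — the
  distortions the pretreatments exist to remove — as the dominant
  nuisance terms.
* Contents default to the embedded determination table's empirical
  distribution (including its one high outlier at 1.41 % w/w), so
  synthetic studies share the reference data's y-range; a uniform
  source over 0.12–0.52 % w/w is available.
* Reproducibility: every sample draws from its own substream
  (`default_rng([seed, index])`), so enlarging a dataset never
  perturbs existing samples.

What passing tests on these data show: the pipeline machinery —
scatter correction, differentiation, windowing, factor selection,
metrics — is internally correct and recovers known ground truth under
the stated noise model, and scatter-correcting pretreatments
measurably beat non-correcting ones when scatter is present. What
they do not show: performance on real powders, where particle-size
effects are wavelength-dependent (not a global affine distortion),
matrix variation is larger and structured, and reference values carry
their own error. Figures of merit on synthetic data are accordingly
optimistic; with the defaults above the full pipeline reaches
cross-validated R² ≈ 0.994 and RPD ≈ 14 (median over ten seeds),
comfortably above the R² = 0.9878 / RPD = 5.513 regime reported for
comparable real-world calibrations.

A known interaction deserves note: MSC's per-spectrum slope absorbs
part of the analyte's own signal, which makes the corrected analyte
amplitude slightly nonlinear in content. The effect grows with the
analyte's share of total absorbance and with distance from the mean
content — the high-content outlier is the worst case, and its
leave-one-out error dominates PRESS in most synthetic runs. This is a
property of MSC itself, not of the implementation.

## Numerical conventions

* Wavenumber axes are stored strictly ascending (instruments report
  descending; files are reordered on read) and must lie within
  3800–12500 cm⁻¹.
* Window bounds are inclusive on both ends.
* SNV on a constant spectrum, MSC with vanishing slope, and R² with
  zero content variance raise errors naming the offending sample.
* Spectral CSV round trips are exact (shortest round-trippable
  decimal representation on write).
* Model files are versioned JSON carrying the axis, windows,
  pipeline spec, MSC reference, centres and regression vector, so
  prediction can run standalone.

## Problem sizes

Default validation runs use 150 samples × 1501 spectral points, LOO
over 120 calibration samples with up to 10 factors, and a 10
pipeline × 6 window-set grid (60 cells); one pipeline evaluation
takes well under a second and the full grid about a minute on one
CPU.
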