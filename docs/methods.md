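# Methods

This note documents the models, conventions and calibration behind `petqa`:
what the pipeline computes, what the synthetic-scan generator emulates, and
which choices were genuinely open.

## 1. Normalization and display conventions

Every volume is scaled by a single factor so the global maximum voxel equals
100. Because one factor scales the whole 3D grid, all voxel ratios — and
hence the relative noise structure — are unchanged; the normalization only
regularizes scale across scanners. Display images sum transaxial slices
into ~1-cm slabs (slab count = ⌈n·t/10 mm⌉) and magnify bilinearly so the
phantom outline spans 200 of 256 pixels. The magnified grid is used only
for report images; every metric is computed on the native reconstructed
grid, where a 40-mm ROI samples on the order of 100–150 pixels.

## 2. Localization

The analysis slice is the one containing the global maximum voxel (ties
break to the lower slice index). The global maximum is assumed to lie in
the hottest (25-mm) cylinder; the angle from the phantom centroid to it
anchors the insert ring, and the remaining inserts are placed by the known
inter-insert angles of the configured layout (placement is therefore
equivariant under phantom rotation). The centroid comes from a threshold
mask with holes filled, so cold inserts do not bias it. Hot-insert ROIs are
re-centered on their local maximum within the original footprint. The 8-mm
ROI emulates the visual-verification step of routine QA reading: when
automatic re-centering lands more than 6 mm from the a priori insert
position, the ROI is re-placed there and flagged `manually_placed`. A
manually placed ROI is subsequently fitted about its geometric center, not
a local maximum.

ROI sampling uses the pixel-center-inside-circle rule with a strict
inequality; the sample count is pure geometry, independent of image
content.

## 3. Radial curve fits

The ROI sample is transformed to polar coordinates about the fit center
(the ROI maximum, or the ROI center for manual placements; maximum ties
break to the lowest (row, col)).

**Cubic fit.** F(r) = F₀ + F₁r + F₂r² + F₃r³, ordinary least squares over
all pixels, solved in one linear step (the iterative χ²-tolerance language
below applies only to the nonlinear Gaussian fit). An angle-averaged
variant (`binned=True`, one point per distinct radius) is available but off
by default. A profile with fewer than 5 distinct radii, or a singular or
ill-conditioned normal matrix, yields `converged=False` and zeroes all
downstream metrics.

**Coefficient uncertainties.** σ(F_N) defaults to the counting-statistics
("data-noise") convention: per-point measurement variance ≈ the mean count,
so σ(F_N) = √(mean counts) · √((XᵀX)⁻¹_NN), *not* rescaled by the fit
residuals. This is the convention of classical fitters given measurement
errors derived from the data noise, and it is what places the
polynomial-fit SNR of background ROIs near 1–3 and of 8-mm lesions near
5–15, the scales on which the metric operates here. The residual-scaled
(SEE) convention is available as `sigma_mode="residual"`.

**Gaussian fit.** G(r) = G₀·exp(−((r−G₁)/G₂)²) + G₃ over signed radii
(positive right of center, negative left; on-column pixels take the row
sign). G₀ is the amplitude *above* the fitted background G₃. Note the
exponent carries no factor ½, so G₂ is not a standard deviation; for this
form the true FWHM is 2√ln2·G₂ ≈ 1.665·G₂ even though G₂ is loosely called
a width. The fit is a damped gradient-expansion (Levenberg–Marquardt)
iteration with deterministic initialization (G₀ = max − median, G₁ = 0,
G₂ = 2 px, G₃ = median), at most 20 iterations, and convergence declared
when successive χ² values differ by less than 10⁻³ (after which a short
undamped Gauss–Newton polish refines the parameters without altering the
convergence decision). Divergence, a singular system, or a non-physical
width (G₂ ≤ 0 or far wider than the profile) is reported as
non-convergence — never an exception — and zeroes the Gaussian metrics.
Non-convergence is informative: it occurs on roughly a third of simulated
background ROIs, rarely on 8-mm lesions, and essentially never on the
larger cylinders.

**χ² convention.** The reported goodness-of-fit is Poisson-weighted,
χ² = Σ (y − ŷ)²/max(y, 1); the same quantity drives the Gaussian
convergence test. Parameter estimation itself is unweighted.

**Metrics.** Polynomial-fit contrast (F₀ − F(r_max))/(F₀ + F(r_max)) with
r_max the largest radius present; polynomial-fit SNR
((F₀ − F(r_max))/σ(F₀))², the exact analog of the Gaussian (G₀/σ(G₀))² —
both divide a fitted amplitude-above-far-field by the uncertainty of the
central coefficient. The plain intercept form (F₀/σ(F₀))² is available as
`snr_mode="intercept"`. A negative fitted amplitude scores 0 (no lesion
evidence). The Gaussian integral is computed literally as (G₀ − G₃)·G₂;
with G₀ the amplitude this goes negative whenever the amplitude is below
the fitted background level (as for sub-centimeter lesions), so in ROC use
its orientation is resolved automatically — it is retained in this form as
the citable formula.

## 4. Q-Q, GLCM and histogram metrics

**Q-Q.** Target-ROI quantiles are plotted against quantiles of a background
ROI taken from the uniform section (a slice without inserts — using the
same-slice central ROI as its own reference would be degenerate). Unequal
sample sizes are interpolated onto min(n_t, n_b) evenly spaced quantiles.
An ordinary least-squares line is fitted to the upper half (pairs at or
above the median background quantile, inclusive on ties); slope ≠ 1 and
intercept ≠ 0 are flagged by t-tests at a configurable α = 0.05, and the
continuous slope/intercept serve as ROC scores.

**GLCM.** The ROI patch is quantized to 64 equal-width levels over its own
min–max range (a common texture default that preserves noise texture at
~100-pixel ROIs; configurable). Co-occurrences are accumulated for the four
unique 1-pixel offsets (E, S, SE, SW), pooled, symmetrized and normalized;
pixels outside the circular ROI join no pair. Features: energy Σp²,
entropy −Σp·ln p, inertia Σ(i−j)²p, homogeneity Σp/(1+|i−j|), correlation
Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ). A constant patch returns the degenerate contract
(energy 1, entropy 0, inertia 0, homogeneity 1, correlation 0). Each
feature is additionally normalized per phantom to its maximum across the
hot-insert and background ROIs. The implementation accumulates pairs
directly because library co-occurrence routines do not support the
circular-ROI mask; it is verified against a brute-force pair-enumeration
oracle.

**Histogram.** Mean, variance (n−1), Fisher skewness g₁, excess kurtosis
g₂, and the operational SUV ratios: suv_max and suv_mean are the ROI
maximum and mean over the central background ROI mean (the only reading
under which the background's own suv_mean is identically 1). These are
voxel-ratio SUVs — no injected-dose normalization is involved.

## 5. ROC, agreement and group statistics

Empirical (trapezoidal) ROC with orientation chosen so AUC ≥ 0.5 and
recorded; Hanley–McNeil standard error; Youden-optimal threshold with ties
resolved toward higher specificity; sensitivity/specificity/accuracy
exactly reproducible by applying `orientation·score ≥ orientation·threshold`
to the inputs. Paired AUC differences use the DeLong test on scores in
their given orientation (re-orienting each metric first would fold the null
distribution and make the test conservative). Reader agreement uses
unweighted Cohen's kappa on the 5-level or dichotomous scale with the
conventional strength bands (≤0.20 poor … >0.80 very good); an ROI is
"visible" when the mean reader score strictly exceeds 1. Group comparisons
gate on a normality test (D'Agostino–Pearson χ² omnibus, Shapiro–Wilk below
n = 8) at α = 0.05 to choose t-test/ANOVA versus
Mann–Whitney/Wilcoxon/Kruskal–Wallis.

## 6. The synthetic phantom-scan generator

The generator works in the post-reconstruction image domain; sinograms,
scatter and randoms are not modeled. Its purpose is to emulate the
*statistics* of reconstructed multi-scanner QA archives well enough that
the metric pipeline faces realistic discrimination tasks.

Per phantom: an anti-aliased relative-activity map (bath 1.0, hot cylinders
`contrast_ratio`, cold inserts 0; boundary pixels area-weighted by 4×
oversampling) is convolved with an isotropic Gaussian whose FWHM is the
effective scanner + reconstruction blur, scaled to the background count
level, multiplied by a smooth per-phantom non-uniformity field, and
degraded with additive noise replicated independently across slices.
Cylinders are axially uniform; inserts occupy a central axial band (about
half the slices, jittered) so slice localization is a real task and the end
slices provide the uniform section.

Noise model (all defaults calibrated once, together, against the reference
cohort statistics; see §7):

- marginal: variance-normalized Student-t with per-phantom tail weight
  `noise_df` (default 15) — reconstructed voxel values are not normal, and
  occasional strong positive kurtosis is characteristic;
- spatial correlation: the field is smoothed to a 2-mm FWHM correlation
  length and variance-restored — effectively near-white at 3–4 mm pixels,
  which is what the extreme-value statistics (raw contrast, max-SUV) and
  the small background fit amplitudes jointly require;
- amplitude: pixel SD = `noise_rel_sd`·bg at background level (default
  0.10·42 ≈ 4.2 counts), fading as √(mean/bg) below background and as
  (mean/bg)^−0.8 above it. The negative hot-side exponent is an effective
  description of iteratively reconstructed, normalized QA images, whose
  hot plateaus show far lower relative noise than the bath — without it the
  25-mm maximum-SUV overshoots its reference value by ~0.5;
- non-uniformity: a multiplicative smooth field (default 6% rms, 65-mm
  scale) emulating residual scatter/attenuation-correction and fill
  artifacts. Radial fits absorb it; max/mean SUV ratios referenced to the
  central background ROI do not — this is what spreads the hot-insert SUVs
  across a cohort and keeps maximum SUV a mediocre classifier, as observed
  on real archives.

Cohort simulation draws per-phantom parameters from truncated normal
ranges: pixel size 3.3 ± 0.3 mm in [2.9, 4.0] (so a 40-mm ROI samples
~100–150 pixels), blur 12.0 ± 0.6 mm FWHM in [10.8, 12.8], fill ratio
2.5 ± 0.12 in [2.3, 2.75], relative noise 0.10 ± 0.022 in [0.055, 0.145],
tail weight 15 ± 8 in [5, 50], non-uniformity 6 ± 2.5% in [0, 11%]. Each
phantom gets an independent sub-stream of the master seed; cohorts are
exactly reproducible.

## 7. Calibration of the defaults

The default blur is the one prescribed calibration constant: it was fixed
once, within the physically plausible 8–13 mm whole-body range, so that the
simulated cohort reproduces the reference maximum-SUV triple (background
≈ 1.3, 8-mm ≈ 1.4, 25-mm ≈ 2.4). Three consistency arguments anchor the
noise defaults rather than free tuning: (i) the background raw contrast
(≈24%) and background max-SUV (≈1.3) jointly pin the within-ROI pixel SD
near 4.2 counts at a mean of 42, with the quoted ±5 spread emerging as the
pooled within-plus-between-phantom variability; (ii) the normalization
construction (global max = 100 ≈ 2.4 × background mean) implies a
near-noise-free 25-mm plateau, fixing the sign of the hot-side noise
exponent; (iii) the reference per-ROI pixel counts (109–145) fix the
cohort pixel-size band. With these defaults a 65-phantom cohort lands at
background max-SUV ≈ 1.26–1.29, 8-mm ≈ 1.44–1.49, 25-mm ≈ 2.45–2.56,
background raw contrast ≈ 26–30%, background polynomial-fit contrast
≈ 6.5–8%, polynomial-fit SNR AUC ≈ 90–98% with Youden sensitivity mostly
≥ 89% for the 8-mm task — all computed fresh by `scripts/acceptance.py`
and the acceptance tests, never hard-coded.

## 8. What the simulator does and does not show

Passing the simulated-cohort tests demonstrates that the pipeline computes
its metrics correctly, that the calibrated generator reproduces the
reference cohort statistics, and that under those statistics the radial
curve-fit metrics dominate max-pixel metrics for sub-centimeter
discrimination. It does not demonstrate performance on real scanner data:
the generator has clean cylindrical geometry, perfectly known insert
positions, axially uniform inserts, isotropic Gaussian blur and a
stationary (up to the smooth field) noise model; real reconstructions add
scanner-specific texture, edge artifacts, misalignment and fill errors it
does not emulate. The Youden operating point of a 65+65-observation ROC is
intrinsically jittery (a few percentage points between cohort seeds), so
single-cohort sensitivity figures carry that spread; the metric *ranking*
is assessed on seed-averaged AUCs.

## 9. Known limitations

- 2D analysis only: fits use a single transaxial section, matching the
  cylindrical-insert geometry; no 3D stacked-slice fitting.
- The Gaussian integral is kept in its citable printed form even though the
  amplitude convention makes it negative for weak lesions; orientation
  handling in ROC absorbs the sign, but its absolute values are not
  comparable to height-times-width summaries defined with a total-peak
  convention.
- Manual-override emulation uses the a priori (ground-truth) insert
  position; a human operator would add a small placement error.
- DICOM support covers single-frame PET series with uniform geometry;
  multi-frame and vendor-private variants are untested.
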