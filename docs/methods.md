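# Methods

This note documents the models and conventions behind `fractomics`: what
each stage computes, the parameters that matter, what the synthetic data
emulate, and the numerical choices that had to be fixed where more than
one convention was defensible.

## Image model and spatial convention

A patient is represented by a scalar 3-D volume and a binary ROI mask on
the same grid, stored `(slice, row, col)` with the slice axis the
anatomical through-plane axis. The default phantom geometry mirrors a
typical rectal staging T2-w acquisition: 0.8 × 0.8 mm in-plane spacing
and 3 mm slice thickness. Because through-plane spacing is nearly four
times coarser than in-plane, every filter and texture matrix operates
per slice in 2-D; no isotropic resampling is applied, and no
registration between mismatched grids is attempted (a mask on a
different grid is an error, not a resample).

## Preprocessing

**Laplacian-of-Gaussian filter** (before first-order and texture
features). The single scale parameter is the Gaussian σ in millimetres
(`log_kernel_mm`, default 0.4 mm, i.e. 0.5 px at 0.8 mm spacing),
converted to pixels per axis. Implementation detail that matters at
sub-pixel σ: a sampled Gaussian-second-derivative kernel does not sum
to zero, so it leaks a DC response (a constant image maps to a non-zero
constant). The filter is therefore implemented as Gaussian smoothing
followed by the exact discrete Laplacian `[1, −2, 1]/h²` per in-plane
axis, which annihilates constants identically and is linear by
construction. Tests verify zero response on constants, linearity, and
agreement with direct 2-D convolution against the filter's own impulse
response in the image interior.

**Intensity-based (IB) normalization** (before fractal features). ROI
intensities are clipped to the 1st/99th percentiles of the ROI
histogram (linear-interpolation percentiles) and affinely rescaled to
[0, 1]. This makes everything downstream invariant under positive
affine rescaling of the raw intensities — a property the test suite
asserts end-to-end for the full fractal feature set. A constant ROI
(p1 = p99) maps to all-zeros and raises a degenerate flag rather than
an error, so downstream stages can emit explicit missing values.

**Threshold subpopulations.** A subpopulation mask selects ROI voxels
with normalized intensity in `[lo, hi)`; the upper bound is closed when
`hi = 1` so that masks over a partition of [0, 1] tile the ROI exactly
(asserted as a property test). The default level set is
`{0, 0.10, 0.30, 0.50, 0.70, 0.90, 1.0}`: the interior levels step by
20%, include the 30% and 50% levels the headline feature needs, and the
C(7,2) = 21 ordered pairs yield the documented 84 fractal features.
The level set is configurable because other level conventions exist.

## Fractal features

For each threshold pair the subpopulation is computed per slice and its
box-counting fractal dimension estimated: the pattern is cropped to its
bounding box, a single-offset box grid is anchored at the origin
(partial edge cells count; no offset minimization), and FD is the
least-squares slope of log(count) against log(1/size) over a dyadic
ladder (1, 2, 4, … up to half the shorter side, minimum three sizes).
Slices on which the subpopulation is empty are skipped — the FD of an
empty set is undefined, and counting it as zero would bias the
aggregates. Per pair, min/max/mean/median over the slice FDs are
emitted; `fractal_maxFD_30_50` is the max aggregate of the (0.30, 0.50)
pair. On exactly self-similar fixtures with matched ladders the
estimator is exact: FD 2 for a filled square on the dyadic ladder, and
log 8 / log 3 ≈ 1.8928 for the level-5 Sierpinski carpet on the
triadic ladder, both verified to tight tolerances; the box counter
itself is verified against a brute-force grid scan on random patterns.

## Texture and first-order features

Feature lists follow the IBSI reference nomenclature, selected to the
documented family cardinalities: 22 first-order, 22 GLCM, 18 GLRLM, 16
GLSZM. The GLRLM family carries the 16 canonical descriptors plus the
two matrix marginal means (mean run length, run-weighted mean gray
level) to reach its cardinality of 18. Matrices are mask-aware: only
pixel pairs, runs and zones entirely inside the ROI contribute. GLCM
uses distance 1, four 2-D directions, symmetrized and summed before
normalization; GLRLM sums maximal runs over the same four directions;
GLSZM labels 8-connected constant-level zones. Intensities are
discretized to a fixed bin count (default 32) over the global ROI range
of the LoG-filtered image. Descriptors are computed per slice and
averaged over non-empty slices. Degenerate inputs (e.g. a constant ROI,
where GLCM correlation divides by zero variance) yield an explicit
`None` sentinel, never NaN. Matrix construction is verified against
independent brute-force enumeration oracles (explicit pair loops, line
walks, flood fill) on random slices.

Morphology (14 descriptors, mm units) uses voxel-count volume, a
marching-cubes surface mesh, convex-hull maximum 3-D diameter, and
principal-axis lengths from the voxel-coordinate covariance. The mask
is pre-smoothed with a 0.5-voxel Gaussian before meshing: meshing the
raw binary raster overestimates curved surfaces by roughly 8%
(staircase artifact), which would push a digital ball's sphericity to
~0.92; with the pre-smoothing a radius-20 ball scores > 0.95 while
flat-faced shapes remain essentially unaffected at this width.

First-order kurtosis is excess kurtosis; variance is the population
moment; moment ratios of a constant ROI are defined as 0; entropy and
uniformity use the fixed-bin-count histogram.

With the 84 fractal features the full battery is 14 + 22 + 22 + 18 +
16 + 84 = 176 per patient, a contract asserted in tests.

## Statistical pipeline

**Univariate screen.** Feature-vs-outcome differences are tested with
the t-test when Shapiro–Wilk accepts normality (p ≥ 0.05) in *both*
outcome groups, otherwise Wilcoxon–Mann–Whitney. No multiplicity
correction is applied at this stage. Constant features and features
with fewer than three values per group are excluded with a flag.

**Logistic model.** Single-feature maximum-likelihood logistic
regression (IRLS via statsmodels), Wald standard errors and two-sided
p-values. Perfect separation is detected up front and raised as a named
error: the MLE does not exist and a silently diverged fit would be
worse than no fit.

**ROC.** AUC is the normalized Mann–Whitney statistic with ties counted
one half (verified against exhaustive pair counting, and invariant
under strictly monotone score transforms). The 95% CI is a
class-stratified percentile bootstrap, default 2,000 resamples. The
operating point maximizes Youden's J over observed thresholds
(prediction positive at score ≥ threshold); ties in J are broken toward
the higher threshold, i.e. higher specificity.

**Cross-validation.** Stratified 3-fold, 5 iterations by default, fresh
shuffles per iteration, giving 15 fold AUCs summarized as mean ± SD.
Folds are stratified because the 5yDFS event rate is low and
unstratified folds can end up single-class. If a training fold is
perfectly separable, the fold is scored by the feature itself, oriented
by the training class means — the ranking the diverging MLE converges
toward — rather than aborting the whole CV.

All randomness flows from user-supplied seeds; the CLI fans a single
global seed out to named sub-streams (cohort, bootstrap, CV) so stages
are independently reproducible, and every report embeds the config hash
and seed.

## Regimen decision

With per-cohort models `logit p = β₀ + β₁·FD`, the curves cross at
`FD* = (β₀,noOXA − β₀,OXA) / (β₁,OXA − β₁,noOXA)`; for the shipped
reference coefficients FD* ≈ 1.545, and the OXA model predicts the
higher 5yDFS everywhere above it. The recommendation reports the
regimen with the higher predicted probability unless the difference is
within `equivalence_margin` (default 0.02 absolute probability — near
and below the crossing the reference curves differ by about one point,
which no clinician would act on). Outputs are always labelled
model-predicted probabilities; the module deliberately produces no
treatment-advice language.

## Synthetic data: what it does and does not emulate

The phantom is an ellipsoidal ROI (default radius 18 mm on a 16 × 64 ×
64 grid at 3 × 0.8 × 0.8 mm) filled with base intensity 100 plus a
spectral-synthesis fractional-noise texture: power-law-filtered white
noise with spectral exponent β = 4 − 3·heterogeneity, amplitude
25·heterogeneity, plus optional white Gaussian noise. This gives a
monotone, controllable relationship between the `heterogeneity` knob
and the estimated FD of intensity subpopulations (verified over
repeated seeds), which is exactly what the pipeline's tests need. It
does *not* emulate rectal anatomy, bias fields, partial-volume effects,
scanner-dependent intensity scales or multi-sequence MRI — so passing
tests demonstrate the computational correctness and calibration of the
pipeline, not clinical performance on real cohorts.

Cohort tables draw `maxFD_30_50` uniformly on a configurable interval
(default [1.4, 2.0], straddling the decision point so both outcome
classes occur) and sample the binary outcome from the logistic
generative model. Parameter-recovery tests confirm that refitting
recovers the generative coefficients within Wald error at n = 5000 and
that the error shrinks as n grows.

## Known limitations

- Real-cohort performance metrics (AUCs near 0.67–0.75, sensitivities,
  specificities) cannot be reproduced without patient data; the test
  suite substitutes property-based checks on synthetic cohorts.
- DICOM RT-STRUCT contour parsing is not implemented; masks must arrive
  as label volumes on the image grid.
- The exact membership of published radiomic feature panels varies
  between software packages; here the family cardinalities are the
  binding contract and the member lists are documented above.
- 3-D box counting, lacunarity and multifractal spectra are out of
  scope, as are wavelet and NGTDM texture families.
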