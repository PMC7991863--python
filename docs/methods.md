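# Methods

## Feature definitions and conventions

All features are *first-order*: functions of the ROI's gray-level
multiset only, invariant to spatial rearrangement. Conventions that had
to be fixed for determinism:

* **Moments.** Population central moments (divide by n). Kurtosis is the
  Pearson ratio m₄/m₂² — a Gaussian scores 3 — not the excess form.
  Skewness uses the standard sign convention (long right tail positive).
  Descriptions of skewness in parts of the clinical literature invert
  this sign verbally; the standard convention is implemented.
* **Median.** For even n, the midpoint of the two central order
  statistics.
* **Entropy and uniformity.** Computed on the normalized histogram;
  entropy in bits (log₂). Default binning is one bin per integer gray
  level spanning [⌊min⌋, ⌊max⌋] — with a few hundred occupied gray
  levels in a typical ROI this yields entropies of the magnitude
  clinical reports print (≈ 6 bits). Binning is configurable
  (`count:<k>` equal-width bins, or `width:<w>`) because published
  in-house pipelines rarely state theirs; note that a single binning
  cannot simultaneously reproduce every published entropy *and*
  uniformity value, so uniformity magnitudes are not comparable across
  binning choices. Bins are half-open, last bin closed; counts always
  conserve n.
* **Size percentages.** Pixel proportions against the μ ± σ thresholds:
  %L strictly below μ−σ, %U strictly above μ+σ, %M the remainder.
  Boundary pixels count as middle — "area under the curve" is ambiguous
  for discrete data, and a fixed boundary rule makes the partition exact:
  %L+%U+%M = 100 to 10⁻⁹ on every input.
* **Degenerate (constant) ROI.** Entropy 0, uniformity 1, bands
  (0, 0, 100) — the analytic limits — while skewness and kurtosis are
  *undefined* (NaN in the panel; the scalar functions raise). Reporting
  0 would fabricate a moment that does not exist.
* **Area.** member-pixel count × row spacing × column spacing / 100
  (cm²); spacing comes from DICOM `PixelSpacing`, the NIfTI zooms, or a
  JSON sidecar. A raster without a sidecar is an error, never a default.

## Phantom model

The generator emulates a case-control study of midsagittal
corpus-callosum texture: per arm, a group model holds the group-level
ROI moments, between-subject SDs for the per-subject mean and SD, and an
ROI-area distribution. The shipped defaults are the study conditions:
20 controls (mean gray level 336.56, between-subject SD 147.21;
within-ROI SD 31.26 ± 13.76; skewness −2.50; Pearson kurtosis 13.80;
area 5.64 ± 0.69 cm²) versus 19 cases (476.10 ± 46.09; 75.49 ± 11.47;
−2.58; 10.34; 6.07 ± 0.94 cm²), on a 256 × 256 grid at 0.9375 mm
isotropic spacing (240 mm field of view).

Design choices, with rationale:

* **i.i.d. ROI intensities.** Every downstream feature is first-order,
  so spatial correlation structure is irrelevant to what the pipeline
  measures; modelling it would add parameters without adding test power.
  Consequently the phantoms say nothing about second-order (texture
  matrix) methods, scanner bias fields or Rician noise — passing tests
  validate the feature computation and statistics, not MR physics.
* **Four-moment sampler.** The study regime (skewness ≈ −2.5, kurtosis
  10–14) is far outside the skew-normal family (|skewness| < 0.9953,
  kurtosis tied to skewness), so a two-component Gaussian mixture is
  solved numerically: a standardized mixture w·N(m₁,s₁²)+(1−w)·N(m₂,s₂²)
  with mean 0 is fitted by multi-start least squares to unit variance and
  the target skewness/kurtosis, then shifted and scaled. Component SDs
  are bounded below at 0.3 (in target-SD units) so the solution is a
  smooth two-mode histogram rather than a spike-plus-tail; the feasible
  region above the moment bound kurtosis ≥ skewness² + 1 still covers
  the study regime with that floor. The solver is deterministic (fixed
  internal restart sequence), caches solutions, and verifies the solved
  moments to ~10⁻⁶ before sampling; an infeasible target (kurtosis below
  the bound) is a parameter error. `skew_normal` requests inside the
  family's range use an exact Azzalini moment match; outside it they
  fall back to the mixture (default kurtosis skewness² + 3 when
  unspecified).
* **Per-subject variation.** Subjects draw their target mean and SD from
  normals with the group's between-subject SDs (clamped so the subject's
  bulk stays inside the clip range, and SD ≥ max(1, 10% of the group
  SD)); skewness/kurtosis are held at the group values so each arm
  shares one solved mixture. Clipping to [value_floor, value_cap]
  (defaults 0–4095) and rounding to integer gray levels slightly bias
  the realized moments; at the default parameters both effects are well
  under the sampling noise of a ~640-pixel ROI.
* **ROI geometry.** A parametric C-shaped arc band (¾ of an annulus,
  seeded orientation and center jitter), built by ranking pixels on
  |r − R| within the angular span and taking exactly
  round(area·100/pixel-area) pixels — the realized area is exact up to
  half-pixel rounding, always within the 2 % contract. Tiny targets, or
  bands that would not fit or not connect, fall back to a compact disk
  accreted by center distance, which is provably a single 8-connected
  component of exact count; connectivity of every mask is verified at
  generation time. Anatomical realism is deliberately out of scope: only
  area and the intensity distribution matter downstream.
* **Background.** The study design gives no background statistics, so
  the surround is a free, documented choice: N(60, 15) clipped at 0 —
  dim and clearly separated from ROI intensities. It never enters
  feature extraction (masked out); it exists so images look like images
  and so mask/image congruence is exercised.
* **Determinism.** All generation flows from a single seed through
  `numpy.random.SeedSequence` spawning (cohort → parameter stream +
  per-subject streams → mask/background/ROI streams). Identical spec and
  seed give bit-identical images, masks, tables and reports.

## Statistics

Per feature, both groups are screened with a one-sample KS test against
a normal with the group's own mean and SD; if both screen p-values
exceed 0.05 the groups are compared with a pooled-variance Student's
t-test (df = n₁+n₂−2), otherwise with a Mann–Whitney U test (midrank
ties; exact enumeration when n₁+n₂ ≤ 12 without ties, else the normal
approximation with tie and continuity correction). All p-values are
two-tailed; no multiple-testing correction is applied — mirroring common
clinical practice — and every comparison table carries a footer saying
so. Choices within that procedure:

* The KS screen uses the asymptotic distribution with estimated
  parameters (the classical statistics-package default); the Lilliefors
  correction is available via a flag. Constant input returns p = 0.
* The pooled (equal-variance) t-test is the default because it is the
  common package default and is exactly computable from group summaries;
  Welch is available via a flag. `summary_student_t` reproduces
  `student_t` to 10⁻¹⁰ on raw samples constructed to match given
  summaries (tested).
* Groups too small to screen (n < 4) default to the t-test rather than
  crashing; with n = 2 per group the rows are produced with wide
  p-values.
* Which test a data-driven screen selects is cohort-dependent, so each
  comparison row records `test_used`.

Type-I calibration: over 500 null cohorts (both arms from one normal,
n = 20 vs 19) the per-feature false-positive rate of the full
screen-then-test procedure at α = 0.05 stays within [0.025, 0.08]
(tested; the screen passes nearly always under the null, so the rate
sits near 0.05).

## Validation scales

The test suite validates at sizes chosen to make tolerances principled:
10⁶-draw samples for limit laws (kurtosis 3.00 ± 0.02, skewness
0 ± 0.01, %M 68.27 ± 0.2 for a Gaussian — tolerances ≈ 4 standard errors
of the estimators), study-sized cohorts (20 vs 19, full 256 × 256
phantoms) for recovery — 200 replicates must flag mean intensity and
entropy as significant with case > control in ≥ 90 % — and 500 null
cohorts for calibration. The brute-force feature oracle (plain-Python
fsum/Counter implementations sharing no code with the package) is
enforced to 10⁻¹² relative error on random pixel lists of length ≤ 50,
excluding only inputs sitting exactly on a μ ± σ band boundary, where
pixel counting is discontinuous and the two implementations may
legitimately round the threshold to opposite sides (the boundary rule
itself is pinned by a dedicated test).

## Known limitations

* 2-D only; slice selection from volumes is explicit, never implicit.
* Proprietary ROI contour formats are not parsed; binary masks are the
  interchange format (the computation consumes pixel sets, not
  contours).
* Stored gray values are analyzed as read; no rescale slope/intercept
  handling.
* Uniformity magnitudes depend strongly on binning and are not
  comparable across pipelines with unknown binning.
* The phantoms validate computation, not acquisition: nothing here
  models scanner noise, partial volume, or anatomy beyond ROI area.
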