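# Methods

## Scope and data model

The package analyses longitudinal attenuation volumes (Hounsfield units)
with integer label masks and two-observer ordinal rating tables. A
`Volume` carries the 3-D HU grid, voxel spacing in mm, a modality tag
(planning-CT or CBCT), and the fraction index; by the study convention
fraction 0 is the planning scan and fractions 1..k are treatment-day
CBCTs. Volumes and masks are NIfTI-1 (spacing in the affine); scan-level
metadata travels in a manifest CSV because NIfTI has no standard slot for
it. Voxel indices are 0-based, physical coordinates are index × spacing
(voxel-center), and the axial slice is a fixed third-axis index.

## ROI metrics

Four scalar metrics summarise a signal ROI *s* and background ROI *b*:

* SNR = (mean_s + 1000) / SD_s. The +1000 HU offset aligns HU with
  linear attenuation so SNR is comparable across scanners; it applies
  only inside SNR.
* C = mean_s − mean_b (HU).
* CNR = 2 (mean_s − mean_b)² / (SD_s² + SD_b²). This non-linear form is
  more sensitive to detectability differences at low contrast than the
  linear CNR, at the price of amplifying noise in high-variance regions.
* CV = SD_s / mean_s × 100 (%).

Phantom ROIs are circles of 25 mm diameter placed on three axial slices
(top/middle/low); per-slice mean and SD are computed over voxels whose
in-plane center distance is ≤ radius, then averaged **unweighted** across
slices, mirroring the slice-wise phantom reading workflow. Patient
reference ROIs (gluteal muscle, remote pelvic fat) are pooled voxel sets.
SD uses ddof = 1. Degenerate ROIs raise (`SNR` with SD = 0, `CV` with
|mean| ≤ 1e-6 HU) instead of returning infinities, so cohort summaries
can never silently contain non-finite values.

Because each slice aggregate can be read per slice or pooled, the ROI
summary retains the per-slice breakdown alongside the aggregate, and the
phantom table reports both.

## Interface shells

Around a target region the mask is partitioned into three disjoint ROIs
using exact Euclidean distance transforms with anisotropic spacing:

* ROI1 — target voxels within 5 mm (inward) of the target boundary. The
  "peripheral part" has no canonical width; 5 mm keeps the rim well
  inside a 20–40 mm organ while staying peripheral, and the width is a
  configuration parameter.
* ROI2 — fat voxels at distance (0, 10] mm from the target.
* ROI3 — fat voxels at distance (10, 20] mm.

Half-open intervals prevent double counting at the 10 mm boundary.
Shell construction never modifies the mask, and empty shells raise with
the offending ROI named. Delta values Δ12 = mean(ROI1) − mean(ROI2) and
Δ23 = mean(ROI2) − mean(ROI3) are stored with the per-ROI statistics and
are recomputable from them to 1e-9.

## Statistical layer

All tests are two-sided at α = 0.05. The implementations are in-package
(they are small, fully specified procedures) and each is verified in the
test suite against an independent oracle: scipy's Friedman and Wilcoxon,
pingouin's ICC(C,k)/ICC(A,k), exhaustive sign enumeration for the
signed-rank null (n ≤ 10), and full permutation for Spearman (n ≤ 7).

* **Friedman**: within-subject ranks with average ranks for ties,
  tie-corrected chi-square with k−1 df. With exactly two conditions the
  test degenerates and the paired Wilcoxon is run instead (labelled).
* **Wilcoxon signed-rank**: zero differences dropped; exact p by dynamic
  programming over the signed-rank null for n ≤ 25 without ties,
  otherwise tie-corrected normal approximation with continuity
  correction. All differences zero yields p = 1 with a warning.
* **Post-hoc**: pairwise Wilcoxon with Bonferroni, p_adj = min(1, m·p).
  The family is either all condition pairs or baseline-vs-each
  (baseline = planning CT by default); the family size is recorded in
  every result. The choice of rank-based pairwise tests keeps the
  post-hoc consistent with the rank-based omnibus test.
* **ICC**: two-way ANOVA mean squares; default is the fixed-raters
  consistency average-measures form ICC(3,k) = (MS_subjects − MS_error)
  / MS_subjects, which ignores a constant rater offset; the
  absolute-agreement variant is available behind a flag. Negative values
  are reported as computed and classified "poor". Bands: <0.50 poor,
  0.50–0.75 moderate, 0.75–0.90 good, ≥0.90 excellent.
* **Spearman**: Pearson correlation of average ranks; exact permutation
  p for n ≤ 9, t approximation with n−2 df otherwise.
* Missing data are removed listwise per analysis, with the exclusion
  count retained; no imputation. Prostate and seminal-vesicle analyses
  form separate testing families.

Because the ICC pooling convention (one subjects×raters table over all
parameters vs per-parameter tables) is ambiguous in practice, the
agreement report computes all three granularities: pooled, per parameter
group, and per parameter.

## Synthetic generator

The generator produces data with the statistical structure the analysis
assumes, not realistic CT physics (no scatter, beam hardening or
reconstruction artefacts — a stated non-goal).

**Phantom**: a water-equivalent cylinder (120 mm diameter) with a
liver-equivalent insert (+60 HU, 30 mm) and a uniform central region,
plus iid Gaussian noise per modality. Default grid 128×128×24 at
1.0507×1.0507×2.0 mm, matching clinical planning-CT sampling.

**Cohort**: pelvic compartments as nested simple solids in a fat matrix
(ellipsoids/boxes): prostate +40 HU, seminal vesicles +35, rectal wall
+30, pelvic fat −100, gluteal muscle +45, bone +700 — textbook values,
all overridable; the study type this emulates reports no absolute
patient HU, so calibration is intentionally free. Per-patient HU jitter
(once per patient) gives between-subject variance. Noise SDs default to
10 HU (planning) and 18 HU (CBCT) so the planning scan has the higher
SNR. The two target regions are deliberately spaced so that the 10–20 mm
shell of one cannot touch the 0–10 mm shell of the other; anatomically
the vesicles sit on the prostate, but overlapping shells would leak the
injected drift of one region into the "stable" outer shell of the other
and break the per-region independence the analysis assumes.

**Drift**: fat within 10 mm of each target gains slope × fraction HU
(default 1.5 HU/fraction) plus a per-scan Gaussian fluctuation
(SD 6 HU) at treatment fractions, emulating day-to-day variability of
treatment-induced change (edema, inflammation). The fluctuation matters:
with voxel noise alone the shell-mean standard error is ~0.3 HU and any
drift would be detectable from the first fraction, whereas biological
variability makes the ROI2-vs-ROI3 separation emerge mid-course. Because
the fluctuation is iid across fractions it leaves the null (slope 0)
calibration of the longitudinal tests untouched. The default slope was
set so the pooled delta-vs-fraction Spearman correlations land near
±0.3, the magnitude typical of this effect.

**Ratings**: latent score = observer intercept (defaults 4.6/4.3) −
0.12 × fraction + a per-scan quality term shared by both observers
(SD 0.6) + independent noise (SD 0.5), rounded and clamped to 1..5, for
seven assessment parameters in two groups (tissue
differentiation/contour sharpness; ART workflow). The shared scan term
carries the between-scan variance that the ICC measures; without it two
raters of the same scans would have nothing to agree on. A decline that
pushes the expected score below 1 at the last fraction warns and clamps.
Assessment time = 120 s + 20 s × fraction + noise (SD 15 s), floored at
1 s.

All randomness derives from the master seed through
`numpy.random.SeedSequence` keyed on (seed, stream, patient, fraction),
so identical configurations are bit-reproducible and adding patients or
fractions never perturbs existing scans.

## Problem sizes and numerical choices

The default cohort grid is 72×72×36 at 2.5×2.5×3 mm (enough for
several-hundred-voxel shells; a full 26-patient run takes seconds);
replicate studies use 48×48×24 at 4 mm so 200 cohort replicates complete
in well under a minute. Distance computations use
`scipy.ndimage.distance_transform_edt`, which is exact for Euclidean
metrics; the test suite checks shell membership against a per-voxel
nearest-neighbour oracle on a 64³ grid. Friedman/Wilcoxon tie handling
follows average ranks; the signed-rank two-sided p is
2·min(P(W ≤ w), P(W ≥ w)) capped at 1.

## What passing tests do and do not show

The generator validates the *pipeline*: that the metrics equal their
closed forms, the shells are geometrically exact, the tests hold their
nominal size and recover injected effects with the right sign and
magnitude, and the whole run is reproducible. It does not validate CBCT
physics: real scans have structured noise, artefacts, registration error
and segmentation uncertainty that simple solids with iid noise cannot
represent, so effect sizes measured on real cohorts are not predicted by
these simulations — only the machinery that would measure them is.

## Known limitations

* Geometry is schematic; organ shapes, partial-volume effects and
  anatomical variability are not modelled.
* The ordinal rating model is a rounded latent Gaussian; it reproduces
  means/SDs and monotone trends but not rater-specific response styles.
* The phantom repeat-stability comparison pairs per-slice metric values
  across all slices intersecting the insert (not just the three protocol
  slices): three paired values cannot reach significance in an exact
  signed-rank test, so the wider pairing is what gives the stability
  check any power. Metrics themselves are still reported on the
  three-slice protocol.
* Friedman p-values use the chi-square approximation, which is liberal
  for very small n; the calibration study (26 subjects) shows the size
  is near-nominal at the cohort sizes used here.
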