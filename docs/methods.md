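# Methods

This note documents the models, conventions and numerical choices behind
`mibiquant`: what the digital phantom emulates (and what it does not), how
each semi-quantitative parameter is defined, and where the design was
genuinely open.

## Coordinate and unit conventions

Volumes are `(nx, ny, nz)` arrays; axis x runs left–right, y
anterior–posterior (the projection axis of a craniocaudal planar view), z
cranio-caudal. Physical coordinates are voxel-centre millimetres with the
origin at the grid centre. Every grid carries a unit tag — `counts`,
`Bq/mL`, or `SUV g/mL` — and operations check it: conversion errors in this
domain are silent and catastrophic otherwise. The default voxel pitch is
2.21 mm isotropic (a typical reconstructed SPECT grid for a breast
protocol) and the default planar pixel pitch 3.20 mm (an 80×80 dedicated
breast camera matrix).

## The digital breast phantom

One subject is a uniform background ellipsoid ("breast", default
160×100×100 mm at 1000 Bq/mL) containing a single ellipsoidal tumor with
three perpendicular diameters (a, b, c). Tumor activity is
`background x TBR_true`, modulated by a multiplicative texture field:
white Gaussian noise smoothed with a fixed 1-voxel-σ kernel and affinely
rescaled so that the realised voxel-level coefficient of variation over the
tumor equals `cov_true` exactly (negative values, possible at extreme CV,
are clamped to zero and logged). The delayed volume equals the early volume
with tumor activity scaled by `1 − washout_fraction` while the background
stays static, so the analytic wash-out rate is exactly
`100 x washout_fraction`; negative fractions model continued accumulation.
Optional voxelwise Poisson noise at `noise_scale` expected counts per Bq/mL
is applied to both volumes. All randomness comes from one seed; identical
(spec, seed) pairs are bit-identical.

The default tumor centre (30.0, 1.5, 1.0) mm is deliberately *not*
commensurate with the voxel lattice. A grid-aligned centre is a degenerate
special case: the voxelization error of the tumor surface then repeats in
phase across the whole boundary and biases any sub-voxel size estimate;
generic (off-lattice) placement is also what real anatomy does. The cohort
simulator additionally jitters the centre per subject.

What the phantom does **not** model: iterative reconstruction and its
resolution properties (no collimator–detector response, no scatter windows,
no partial-volume blur of the tumor boundary beyond voxelization), breast
tissue inhomogeneity, and any physiologic time–activity curve between the
two time points — `washout_fraction` is a phenomenological stand-in, since
no kinetic model is fitted anywhere in the pipeline. Passing tests on these
phantoms therefore validates the *measurement* chain, not robustness to
reconstruction artefacts.

### Planar projection

Planar views are parallel-ray line integrals (plain voxel sums, conserving
total counts): CC sums along y, LAT along x, MLO rotates the volume 45°
about z (linear interpolation) before summing along y. Optional exponential
depth attenuation weights each plane by `exp(-mu * depth)` with the
detector at the low-index face; the default coefficient when enabled is
0.15 cm⁻¹, soft tissue at 140 keV. Attenuation is off by default: the
planar modality applies no attenuation correction clinically, and the
toggle exists precisely to reproduce that bias direction (enabling it
lowers planar TBR, because the tumor's excess counts are attenuated by its
specific depth while the background denominator is attenuated by the
ray-average, which is always milder for a mid-depth lesion). The summed
projection is resampled to the detector pixel pitch by linear interpolation
of the count density, approximately conserving totals; Poisson noise, if
requested, is applied per pixel.

## SPECT quantification

* **Counts → activity.** `Bq/mL = counts / (sensitivity x duration x
  voxel_mL) x 1e6`. The clinical chain does this inside vendor software;
  the formula here is the explicit contract (volume sensitivity in
  cps/MBq), with the exact inverse provided for simulation round-trips.
* **Activity → SUV.** Body-weight SUV with the injected activity
  decay-corrected from injection to scan start using the Tc-99m half-life
  6.0058 h; tissue density 1 g/mL is assumed so SUV carries g/mL. Whether
  the clinical software decay-corrects is not documented publicly; pinning
  it here makes the convention explicit and testable (one half-life of
  uptake time exactly doubles SUV).
* **Delineation.** 42% threshold iso-contour: voxels ≥ 0.42 × the maximum
  *within the user-supplied search region* (emulating the seed click of a
  semi-automatic workstation tool), restricted to the 26-connected
  component containing the maximum voxel. Voxels exactly at threshold are
  included (the inclusive choice is arbitrary but pinned). The manual
  visual-adjustment step of clinical practice is replaced by the
  deterministic connectivity rule for reproducibility. A brute-force
  scan-and-flood-fill reference implementation backs the tests.
* **Background.** Sphere of 30 mm diameter selected by voxel centre; on
  phantoms it is placed at the tumor centre mirrored across the midline,
  mimicking the contralateral healthy breast. A sphere clipped by the grid
  raises, since a truncated background sample would bias every TBR.
* **Parameters.** SD is the population (divide-by-n) standard deviation —
  the sample/population distinction is immaterial at VOI sizes of hundreds
  of voxels but is pinned for exactness. `TLMU = FTV x SUV_mean` holds to
  machine precision by construction. WOR defaults to the mean-based TBR
  (the max-based variant is supported and the choice is recorded in the
  result object, as the convention is genuinely ambiguous in the field).

A note on COV under threshold delineation: a 42% iso-contour *truncates*
the voxel-value distribution at high heterogeneity. At CV ≲ 15% the tumor
histogram lies entirely above threshold and the VOI-measured COV equals
the generating value; at CV ≈ 30% the contour legitimately excludes the
coldest tumor voxels and the measured COV saturates near 20% — an inherent
property of threshold delineation, not an implementation error. Recovery
is therefore validated over the true tumor region, and the monotone
ordering of COV (the clinically relevant content) is additionally
validated through the full delineation pipeline.

## Planar (MBI) quantification

Tumor pixel statistics use an in-view 42% iso-contour, applied to the
*background-subtracted* lesion excess (grey-opening residual): at planar
contrast the raw 42% level sits below the breast tissue itself, so a raw
threshold would leak far outside the lesion. Background ROIs are 3 cm
circles on the CC and MLO views of the contralateral side. The TBR_ave
denominator pools the background pixels of both views (rather than
averaging per-view means); with equal-size ROIs the two coincide, and the
pooled choice is pinned and recorded. COV_norm retains counts units by
construction — it scales with acquisition duration and is flagged as not
comparable across acquisitions.

**Diameter measurement.** The ellipsoid-FTV formula needs three
perpendicular diameters that a physician would measure with callipers.
The deterministic stand-in fits, per view, a two-component model by
bounded least squares: a chord-length dome for the breast background
(`s·sqrt(1 − ((i−c₀)/R₀)² − ((j−c₁)/R₁)²)`, free centre/semi-axes/scale)
plus a chord-length dome for the lesion, the latter convolved with a small
fixed Gaussian whose variance `pixel²/6 + voxel²/12` represents the
resampling blur. A simple full-width-at-fraction threshold rule on a
centroid profile was evaluated first and rejected: its crossing points
shift with any local misestimate of the curved, sloping breast baseline,
and its residual bias (several percent per axis, compounding to >10% in
volume) defeats the planar/volumetric consistency the measurement exists
to test. One body axis is read per view — a from CC's horizontal axis,
b and c from the LAT view's two in-plane axes. The oblique MLO view
contributes to count-based parameters but not to calliper measurement:
its horizontal axis mixes a and b through the 45° obliquity, and
recovering b by inverting `w² = (a² + b²)/2` doubles the error of both
measurements, so the direct LAT reading is preferred.

## Cohort statistics

Shapiro–Wilk at α = 0.05 gates every branch: mean (SD) vs median (IQR)
summaries (quartiles by linear interpolation, type-7), paired t-test vs
Wilcoxon signed-rank on paired differences (exact null for n ≤ 25, normal
approximation with continuity correction above; all-zero differences give
p = 1 by convention), independent t-test vs Mann–Whitney U for unpaired
arms. Spearman's rank correlation accompanies every paired comparison. A
Brown–Forsythe (median-centred Levene) test is provided for
spread-vs-spread claims. No multiple-testing correction is applied — the
report mirrors single-comparison conventions common in small imaging
cohorts, and readers should treat the p-values accordingly.

## The synthetic cohort

`run_pipeline` simulates n = 18 subjects by default: largest tumor diameter
uniform in 24–36 mm (the enrolment floor was 2 cm), the other two axes at
0.7–1.0 and 0.6–0.95 of it; contrast uniform in 3.3–9.6 (the range over
which the 42% delineation was validated on physical phantoms);
heterogeneity uniform in 5–25%; wash-out fraction normal (0.2, 0.3) clipped
to [−0.6, 0.8], spanning both tracer loss and accumulation; body weight
normal (70, 10) kg clipped to [50, 95]; 600 MBq injection, scans at 5 and
90 min p.i. One randomly chosen subject lacks the delayed scan, so WOR
comparisons run on n−1 — reproducing the realistic missing-data pattern.
Per-subject seeds derive from the master seed; reruns are byte-identical.

## Problem sizes

Validation sweeps use single-subject phantoms of ≈ 80×50×50 voxels; the
segmentation reference check runs 100 random volumes up to 32³; the cohort
stage runs 18 subjects twice (for the determinism check). These sizes make
every stage's ground truth exactly computable while keeping the full
validation suite in the seconds-to-minutes range on one core.

## Known limitations

* No partial-volume effect at the tumor boundary beyond voxelization, so
  FTV recovery here is easier than on reconstructed clinical data; the
  recovery bound should be read as a best case.
* The planar diameter measurement assumes one dominant, roughly
  ellipsoidal lesion well inside the field of view; diffuse growth or
  chest-wall lesions — excluded by manual judgment in clinical reading —
  are out of scope (the cohort table carries a per-lesion exclusion flag
  instead of inferring it).
* COV_norm is reported as-is in counts units.
* Single lesion per volume; no multi-focal batching.
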