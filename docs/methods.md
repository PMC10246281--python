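# Methods

This note documents the models and procedures implemented in `radtract`,
the assumptions behind them, the numerical choices that were genuinely
open, and what the synthetic phantoms do and do not establish about real
data.

## Data model and coordinate conventions

Streamlines are ordered 3-D polylines in world RAS millimetres; images
are voxel grids with a 4×4 affine, voxel centers at integer 0-based
indices. Tractography formats that store voxel-scaled or corner-based
coordinates (TRK) are normalized to world mm on load via
`nibabel.streamlines`, so no downstream operation ever sees more than
one convention. Voxel membership of a continuous index uses
nearest-integer rounding with ties toward the lower index — the
tie-break is arbitrary but must be fixed for reproducible parcellations.
Nothing assumes isotropic voxels: physical sigmas, voxel volumes and
spacing-aware shape descriptors all go through the affine.

## Streamline geometry

* **Resampling** places *n* points at equal arc length along the
  polyline, preserving the endpoints exactly. Arc length is measured on
  the polyline itself, so resampling can shorten a curve only by corner
  cutting; for smooth streamlines at n at or above the original point
  count this stays well below 1%.
* **MDF** (minimum average direct-flip distance) between two
  streamlines resampled to the same point count is the mean pointwise
  Euclidean distance minimized over reversing one of them. 12-point
  resamplings are used for clustering and orientation (configurable);
  bundle-level geometry does not need more.
* **Orientation alignment** reverses a streamline when its last point is
  strictly closer than its first to the nearest nonzero voxel center of
  a start-region ROI (ties keep the input order, making the operation
  idempotent), or, without an ROI, when the MDF to a reference
  centerline is attained in the flipped orientation. The centerline is
  the pointwise mean of the aligned, resampled streamlines; a cluster
  representative can be substituted via the API.
* **Bundle reduction** runs a single-pass clustering scheme: each
  streamline joins the nearest running-mean centroid within a distance
  threshold (flipping to match) or seeds a new cluster. The threshold
  is found by bisection so the cluster count lands within ±10% of the
  target (default 500, operationalizing "about 500"); if the band is
  unreachable — e.g. heavy exact duplication — the code falls back to
  seeded uniform subsampling to exactly the target. Output centroids are
  deterministic given input order and seed.
* **Traversed-voxel counting** walks the polyline at half the minimum
  voxel size and counts unique voxels; revisits are not recounted. The
  step is oracle-tested against a 10× finer rasterization.

## Parcellation

Training samples are all (coordinate, position-index) pairs of the
reduced bundle resampled to *n* points. The classifier is a one-vs-one
SVM with an RBF kernel and default regularization (linear kernel
available); coordinates are centered and isotropically scaled by the
training cloud's RMS radius so the kernel bandwidth heuristic sees
comparable scales. Prediction happens at voxel centers only — no
sub-voxel soft assignment. The automatic parcel count rounds
`n_voxels / m` to the nearest integer and clamps at 1; `m` defaults to
5 voxels, thick enough to avoid fragmented parcels with too few voxels
for meaningful texture statistics.

The index-labeling scheme has a geometric consequence worth making
explicit: index *k* sits at arc fraction (k−1)/(n−1), so on an idealized
straight tube the optimal decision regions are the *Voronoi cells of the
n index positions* (slab boundaries at midpoints), with half-width end
parcels. The phantom ground truth, the centerline baseline
(nearest-of-n-centerline-points) and the analytic test oracles all use
this same nearest-index convention, so method comparisons are never
confounded by a binning-convention mismatch.

The centerline baseline and a parcel-wise Dice coefficient
(2|A∩B|/(|A|+|B|), defined as 1 when both parcels are empty and 0 when
exactly one is) support the comparisons; on straight tubes the two
parcellations agree almost everywhere, while on strongly fanning
bundles the voxel-space parcellation tracks the streamline-index ground
truth strictly better.

## Radiomic features

The registry fixes names and counts: 18 first-order, 14 shape, 22 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM and 5 NGTDM features — 91 intensity/texture
features per image plus shape on the original geometry only. The
default filter bank holds 11 derived images: Laplacian-of-Gaussian at
σ = 1, 2, 3 mm (physical units, divided by the voxel size per axis;
kernel truncated at 8σ so a constant image maps to ~0) and the 8
sub-bands of a single-level stationary (undecimated) Coiflet-1 wavelet
transform, all on the original grid. Totals: 105 original + 11·91
filtered = 1106 per parcel.

Intensities are discretized per parcel into 32 equal-width bins spanning
the parcel's [min, max] (the maximum maps to the top bin; constant
parcels collapse to bin 1). A fixed bin count rather than a fixed bin
width is the robust default for FA-like maps confined to [0, 1]; both
modes are exposed. Range-relative discretization makes all texture
features invariant to adding a constant to the image.

Texture matrices are built over the 26-connected 3-D neighborhood:
GLCM and GLRLM per each of the 13 unique directions with features
averaged over directions (matrix merging is the alternative, not used by
default); GLSZM zones and GLRLM runs are connected components of each
gray-level set (26-connected and direction-constrained respectively),
counted via labeled-component size histograms; GLDM dependence is 1 +
the number of equal-level 26-neighbors; NGTDM sums per-level deviations
from the mean of the in-mask neighborhood. Degenerate constructs are
pinned: empty matrices yield zeros, zero-variance GLCM marginals yield
correlation 1, logarithms are guarded by machine epsilon, and constant
regions give zero contrast/busyness by construction.

Shape features are computed on a marching-cubes mesh of the zero-padded
binary parcel in physical coordinates (mesh volume by the divergence
theorem, surface area from the triangulation, sphericity
(36πV²)^⅓ / A, maximum 3-D and in-plane diameters from mesh-vertex
pairs, subsampled above 2000 vertices with a fixed seed) plus
principal-component axis lengths (4·√eigenvalue) of the voxel-center
cloud. Single-voxel parcels fall back to voxel-box surrogates for the
axes.

Missing parcels produce rows of flagged NaN, never silent drops;
downstream selection discards NaN-bearing columns instead of imputing.

The classic baseline reduces the image along the tract to a 100-point
mean profile: trilinear samples at every streamline point, each
assigned to the nearest of 100 centerline points, averaged per bin.

## Prediction harness

Per training fold: drop constant columns, greedily drop the later
column of each pair with |Pearson r| > 0.95 (keep-first is the
deterministic tie-break), rank by ANOVA-F (classification) or
F-regression and keep the top 500. Selection statistics never see
held-out rows; a leakage probe in the test suite enforces this.
Classification runs ten differently seeded leave-one-out
cross-validations of a 500-tree random forest with no hyperparameter
tuning; AUROC is pooled over the folds of each seed (one-vs-rest macro
average beyond two classes) and reported as mean ± sd over seeds.
Regression uses a fixed 70/30 split stratified by outcome quartile
(the ratio was an open choice), reporting per-seed test-set Pearson r
with a two-sided t-test p and the MAE; constant predictions are flagged
and reported as r = 0, p = 1. Parcel and feature-class importance are
group sums of per-model mean-decrease-in-impurity importances averaged
over folds and seeds; unselected features contribute zero, and an
unmappable feature raises. Method comparison uses the two-sided
Wilcoxon signed-rank test (exact null up to 25 pairs unless zeros force
the normal approximation) with Bonferroni correction capped at 1.

## Synthetic phantoms

`make_bundle` generates tube (parallel jittered lines), fan (common
trunk over the first 60% of the length, then linear divergence of the
endpoints up to the fan half-angle) and arc (120° circular segment)
geometries, with an envelope mask (visited voxels dilated by 1), a
start-region ROI, and a ground-truth label image rasterized from the
streamlines' nearest-index arc positions by per-voxel majority vote
(ties to the lower label). The default fan half-angle of 60° emulates
the strong cortical fanning where centerline assignment is known to
break down.

`make_subject_image` produces FA-like images: white noise smoothed with
a 4 mm Gaussian kernel, rescaled to [0.3, 0.7] (a plausible FA dynamic
range in white matter), plus additive noise of sd 0.03. Group B
receives, inside the chosen parcel, either a mean shift (+δ, default
0.1) or a texture effect: noise sd multiplied by ρ (default 2) with the
parcel mean re-centered so per-parcel means stay matched — an effect
mean profiles cannot see by construction. Cohorts are balanced, share
one envelope/ground-truth geometry (emulating perfectly co-registered
subjects), and are bitwise reproducible from the seed.

What the phantoms do **not** emulate: real tractography errors
(spurious/premature streamlines), partial-volume and CSF contamination,
anatomically structured FA texture, registration error between
subjects, scanner/site effects, and crossing-fiber geometry. Passing
the end-to-end tests therefore shows that the machinery is correct and
sensitive under its own assumptions, not that effect sizes transfer to
clinical cohorts.

## Problem sizes and defaults in the experiment pipeline

The desk-scale study (`run_cohort_experiment`) uses 25 subjects per
group, an 8-parcel tube on a 26×26×58 grid of 1 mm voxels, the
original-image feature subset (105 features per parcel; the filtered
subsets are available but add nothing to a noise-texture effect), ten
seeds, and the full 500-tree forest in leave-one-out mode. The
parcellation is fit once on the template bundle and reused across
subjects, which is exact under the phantoms' shared-geometry
assumption.

## Known limitations

* QuickBundles-style reduction returns running-mean centroids, which
  smooth high-curvature detail; for parcellation training this is
  harmless, but medoid representatives would be preferable for
  visualizing representative trajectories.
* The GLDM dependence definition (α = 0, strict level equality) and the
  direction-averaging of GLCM/GLRLM follow one common convention among
  several in the radiomics literature; both are configurable at the
  function level but the registry totals assume the defaults.
* Parcel-level ground truth does not exist for real tracts; all
  geometric accuracy statements are phantom-based.
* With very small parcels (≲ 10 voxels) texture matrices become sparse
  and several features degenerate; the automatic parcel-count rule's
  m = 5 default exists precisely to keep parcels above this regime.
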