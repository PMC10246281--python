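# radtract

Radiomic tractometry for diffusion-MRI parameter maps: voxel-space
white-matter tract parcellation with a large-margin classifier, followed
by per-parcel radiomic feature extraction and subject-level prediction
with parcel-importance mapping.

## The problem

Classic tractometry evaluates a scalar map (typically the fractional
anisotropy, FA) along a tract by assigning streamline samples to one of
*n* parcels — either by static resampling of each streamline or by
nearest-point projection onto a tract centerline — and averaging within
each parcel. Both strategies misassign samples where the tract fans or
splits, are biased towards the densely sampled tract core because they
operate in streamline space, and compress the image content along the
tract into a handful of means.

This package takes a different route. The points of the statically
resampled streamlines form a multiclass classification problem: the 3-D
coordinate is the feature and the position index *l* ∈ [1…n] along the
streamline is the class. A support-vector machine fit on these samples
yields decision surfaces that carve 3-D space into parcels respecting
fanning architectures; applying it to every voxel covered by the tract
gives a voxel-space parcellation with no density bias. The number of
parcels can be set automatically as

```
n_auto = round(n_voxels / m)
```

with `n_voxels` the average number of voxels traversed by the
streamlines and `m` the desired parcel thickness (default 5 voxels).
Each parcel then yields a standardized radiomic feature set — 18
first-order statistics, 14 shape descriptors, and 73 texture features
from the GLCM/GLRLM/GLSZM/GLDM/NGTDM gray-level matrices — computed on
the original image and on 11 filtered variants (3 Laplacian-of-Gaussian
scales, 8 stationary-wavelet sub-bands): 105 features on the original
image, 91 per filtered image, 1106 per parcel. For prediction, constant
and highly correlated (|r| > 0.95) features are dropped, a univariate
filter keeps the top 500, and a 500-tree random forest is scored with
repeated, differently seeded leave-one-out cross-validation; summing a
parcel's feature importances localizes the tract regions driving a
prediction.

A synthetic phantom module (bundles with tube/fan/arc geometry,
co-registered FA-like images, two-group cohorts with a localized mean or
texture effect) makes the whole pipeline testable without imaging data.

## Worked example

```python
import radtract as rt

spec = rt.PhantomSpec(shape="fan", length=48.0, radius=3.0, fan_angle=60.0,
                      n_streamlines=150, jitter=0.2, grid_shape=(90, 90, 70),
                      seed=13)
tract, envelope, start_roi, _ = rt.make_bundle(spec)
tract = rt.orient_by_start_roi(tract, start_roi)

n = 8
truth = rt.ground_truth_parcels(tract, envelope, n)
svm = rt.parcellate_voxels(rt.fit_parcellation_model(tract, n, seed=0), envelope)
baseline = rt.centerline_parcellation(tract, rt.compute_centerline(tract, n), envelope)

print(rt.parcelwise_dice(svm, truth, n=n).mean())       # 0.857
print(rt.parcelwise_dice(baseline, truth, n=n).mean())  # 0.832
```

On this fanning phantom the voxel-space parcellation scores a mean
parcel-wise Dice of 0.857 against the streamline-index ground truth,
versus 0.832 for the centerline baseline — the gap sits in the fanning
end parcels, where nearest-centerline assignment mislabels lateral
voxels (run `examples/01_parcellate_phantom.py` for the per-parcel
breakdown). `examples/03_cohort_prediction.py` runs the full desk-scale
study: on a 50-subject cohort with a mean-preserving variance effect in
parcel 3, the per-parcel radiomic features reach AUROC 0.999 ± 0.001
while the 100-point mean-profile baseline stays near chance
(0.619 ± 0.026), and the parcel-importance map puts parcel 3 on top
with importance 0.624.

The `radtract` console script exposes the same steps for on-disk data:
`radtract parcellate`, `radtract features`, `radtract profile`,
`radtract predict` and `radtract simulate`
(see `examples/04_cli_roundtrip.py`).

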