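"""Parcellate a synthetic fiber bundle and compare with the centerline
baseline.

Builds a fanning bundle phantom, trains the voxel-space SVM parcellation
and the classic nearest-centerline-point parcellation with the same
number of parcels, and scores both against the streamline-index ground
truth with a parcel-wise Dice coefficient.
"""

import numpy as np

import radtract as rt

spec = rt.PhantomSpec(
    shape="fan", length=48.0, radius=3.0, fan_angle=60.0,
    n_streamlines=150, jitter=0.2, grid_shape=(90, 90, 70), seed=13,
)
tract, envelope, start_roi, _ = rt.make_bundle(spec)
tract = rt.orient_by_start_roi(tract, start_roi)

n = 8
truth = rt.ground_truth_parcels(tract, envelope, n)
model = rt.fit_parcellation_model(tract, n, seed=0)
svm_labels = rt.parcellate_voxels(model, envelope)
centerline_labels = rt.centerline_parcellation(
    tract, rt.compute_centerline(tract, n), envelope
)

svm_dice = rt.parcelwise_dice(svm_labels, truth, n=n)
cl_dice = rt.parcelwise_dice(centerline_labels, truth, n=n)
print(f"parcels: {n}, envelope voxels: {envelope.count()}")
print("per-parcel Dice vs ground truth (SVM):       ",
      np.round(svm_dice, 3))
print("per-parcel Dice vs ground truth (centerline):",
      np.round(cl_dice, 3))
print(f"mean Dice  SVM {svm_dice.mean():.3f}  vs  centerline {cl_dice.mean():.3f}")
print("Higher is better; the gap concentrates in the fanning end parcels,")
print("where nearest-centerline assignment mislabels lateral voxels.")
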