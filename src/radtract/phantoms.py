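"""Synthetic fiber-bundle phantoms and two-group cohorts.

The generators produce the three ingredients every other module consumes
— a streamline bundle, a co-registered FA-like scalar image in [0, 1] and
binary masks — together with a known ground-truth parcellation, so the
whole pipeline can be exercised and validated without any imaging data.

Geometries:

* ``tube``  — parallel jittered lines along the z axis;
* ``fan``   — a common trunk for the first 60% of the length, then the
  endpoints diverge linearly up to the fan half-angle (the geometry where
  centerline-based parcel assignment breaks down);
* ``arc``   — a circular segment.

Cohorts are two balanced groups whose images differ, inside one chosen
parcel, either by a mean shift (first-order effect) or by a noise-variance
inflation with the parcel mean re-centered (a texture effect invisible to
per-parcel means).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Tuple

import numpy as np
from scipy import ndimage

from .core_io import (
    BinaryMask,
    GridReference,
    LabelImage,
    ScalarImage,
    Streamline,
    Tractogram,
    nearest_voxel,
    world_to_index,
)
from .streamlines import resample_polyline, traversed_voxels


@dataclass
class PhantomSpec:
    """Geometry of a synthetic bundle."""

    shape: Literal["tube", "fan", "arc"] = "tube"
    length: float = 60.0  # mm along the main axis
    radius: float = 3.0  # trunk radius, mm
    fan_angle: float = 30.0  # half-angle, degrees (0 => tube)
    n_streamlines: int = 200
    jitter: float = 0.3  # per-point positional noise sd, mm
    grid_shape: Tuple[int, int, int] = (40, 40, 72)
    voxel_size: float = 1.0  # mm, isotropic grid
    n_points: int = 40  # points per generated streamline
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.radius < 0 or self.n_streamlines < 1:
            raise ValueError("phantom geometry must be positive")


@dataclass
class CohortSpec:
    """Two-group cohort with a localized effect in one parcel."""

    n_per_group: int = 25
    effect: Literal["mean_shift", "texture", "none"] = "texture"
    delta: float = 0.1  # mean shift added in group B (mean_shift mode)
    rho: float = 2.0  # noise-sd multiplier in group B (texture mode)
    effect_parcel: int = 3
    n_parcels: int = 8
    background_low: float = 0.3
    background_high: float = 0.7
    smooth_fwhm: float = 4.0  # mm, background smoothing kernel
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0 or self.rho < 1:
            raise ValueError("need delta >= 0 and rho >= 1")
        if self.n_per_group < 1:
            raise ValueError("need at least one subject per group")


def _grid_reference(spec: PhantomSpec) -> GridReference:
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    return GridReference(spec.grid_shape, affine)


def _axis_points(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-streamline trajectory before jitter, centered in the grid."""
    t = np.linspace(0.0, 1.0, spec.n_points)
    center = 0.5 * np.asarray(spec.grid_shape) * spec.voxel_size
    z0 = center[2] - spec.length / 2.0
    if spec.radius > 0:
        r = spec.radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        ox, oy = r * np.cos(phi), r * np.sin(phi)
    else:
        ox = oy = 0.0
    pts = np.empty((spec.n_points, 3))
    if spec.shape == "arc":
        # circular segment in the x-z plane subtending 120 degrees
        theta = np.deg2rad(120.0)
        R = spec.length / theta
        ang = -theta / 2 + t * theta
        pts[:, 0] = center[0] + R * (np.cos(ang) - np.cos(theta / 2)) + ox
        pts[:, 1] = center[1] + oy
        pts[:, 2] = center[2] + R * np.sin(ang)
        return pts
    pts[:, 0] = center[0] + ox
    pts[:, 1] = center[1] + oy
    pts[:, 2] = z0 + t * spec.length
    if spec.shape == "fan" and spec.fan_angle > 0:
        # trunk for the first 60% of arc length, then linear divergence of
        # the endpoint up to the half-angle
        direction = rng.uniform(0, 2 * np.pi)
        max_off = np.tan(np.deg2rad(spec.fan_angle)) * 0.4 * spec.length
        amount = rng.uniform() * max_off
        ramp = np.clip((t - 0.6) / 0.4, 0.0, 1.0)
        pts[:, 0] += ramp * amount * np.cos(direction)
        pts[:, 1] += ramp * amount * np.sin(direction)
    return pts


def make_streamlines(spec: PhantomSpec) -> Tractogram:
    """Generate only the streamline bundle of a phantom."""
    rng = np.random.default_rng(spec.seed)
    ref = _grid_reference(spec)
    streamlines = []
    for i in range(spec.n_streamlines):
        pts = _axis_points(spec, rng)
        if spec.jitter > 0:
            pts = pts + rng.normal(0.0, spec.jitter, size=pts.shape)
        streamlines.append(Streamline(pts, id=i))
    return Tractogram(streamlines, ref)


def make_bundle(
    spec: PhantomSpec,
) -> Tuple[Tractogram, BinaryMask, BinaryMask, LabelImage]:
    """Generate a bundle plus envelope mask, start ROI and ground truth.

    Returns ``(tractogram, envelope, start_roi, ground_truth_parcels)``.
    The envelope is the set of streamline-visited voxels dilated by one
    voxel; ground-truth parcels bin each streamline's dense points by
    equal arc length into ``spec``-independent ``n_parcels`` (set via
    :func:`ground_truth_parcels`) — here a default of 0 parcels means the
    label image is built later by :func:`ground_truth_parcels`.
    """
    if min(spec.grid_shape) < 2:
        raise ValueError("degenerate grid")
    tract = make_streamlines(spec)
    ref = tract.reference
    streamlines = tract.streamlines

    probe = ScalarImage(np.zeros(spec.grid_shape), ref.affine)
    visited = np.zeros(spec.grid_shape, dtype=bool)
    for s in streamlines:
        vox = traversed_voxels(s, probe)
        visited[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    envelope = BinaryMask(
        ndimage.binary_dilation(visited, iterations=1).astype(np.uint8), ref.affine
    )

    start = np.zeros(spec.grid_shape, dtype=np.uint8)
    first_pts = np.stack([s.points[0] for s in streamlines])
    idx = nearest_voxel(world_to_index(probe, first_pts))
    idx = np.clip(idx, 0, np.asarray(spec.grid_shape) - 1)
    start[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    start_roi = BinaryMask(
        ndimage.binary_dilation(start.astype(bool), iterations=1).astype(np.uint8),
        ref.affine,
    )

    gt = ground_truth_parcels(tract, envelope, n_parcels=5)
    return tract, envelope, start_roi, gt


def ground_truth_parcels(
    t: Tractogram, envelope: BinaryMask, n_parcels: int
) -> LabelImage:
    """Rasterize streamline position indices into voxel labels.

    Each streamline is densely resampled; a dense point at arc-length
    fraction f gets the index of the nearest of ``n`` equally spaced arc
    positions — the same convention by which the resampled training
    points are labeled, and by which the centerline baseline assigns
    voxels.  Every envelope voxel takes the majority vote over all
    streamline points mapping into it (ties to the lower label);
    envelope voxels never visited take the label of the nearest labeled
    voxel.
    """
    shape = envelope.shape
    votes = np.zeros(shape + (n_parcels,), dtype=np.int32)
    dense = 20 * n_parcels
    probe = ScalarImage(np.zeros(shape), envelope.affine)
    for s in t.streamlines:
        pts = resample_polyline(s.points, dense)
        frac = np.arange(dense) / (dense - 1)
        labels = np.floor(frac * (n_parcels - 1) + 0.5).astype(int)
        idx = nearest_voxel(world_to_index(probe, pts))
        inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
        idx, labels = idx[inside], labels[inside]
        np.add.at(votes, (idx[:, 0], idx[:, 1], idx[:, 2], labels), 1)
    out = np.zeros(shape, dtype=np.int32)
    voted = votes.sum(axis=-1) > 0
    # argmax returns the first (lowest) label on ties
    out[voted] = votes[voted].argmax(axis=-1) + 1
    missing = (envelope.voxels > 0) & ~voted
    if missing.any():
        _, nearest = ndimage.distance_transform_edt(~voted, return_indices=True)
        out[missing] = out[nearest[0][missing], nearest[1][missing], nearest[2][missing]]
    out[envelope.voxels == 0] = 0
    return LabelImage(out, envelope.affine)


def make_subject_image(
    envelope: BinaryMask,
    ground_truth: LabelImage,
    group: str,
    cohort: CohortSpec,
    subject_seed: int,
) -> ScalarImage:
    """FA-like image: smooth background + noise, plus the group effect.

    Group B gets, inside the effect parcel, either a mean shift of
    ``delta`` or a noise-sd inflation by ``rho`` with the parcel mean
    re-centered so per-parcel means stay matched across groups.
    """
    rng = np.random.default_rng(subject_seed)
    shape = envelope.shape
    sigma_vox = cohort.smooth_fwhm / (2.3548 * envelope.voxel_sizes)
    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma_vox)
    lo, hi = field.min(), field.max()
    span = cohort.background_high - cohort.background_low
    background = cohort.background_low + span * (field - lo) / max(hi - lo, 1e-12)
    noise = rng.normal(0.0, cohort.noise_sd, size=shape)
    img = background + noise
    in_parcel = ground_truth.voxels == cohort.effect_parcel
    if group == "B" and in_parcel.any():
        if cohort.effect == "mean_shift":
            img[in_parcel] += cohort.delta
        elif cohort.effect == "texture":
            extra_sd = cohort.noise_sd * np.sqrt(cohort.rho**2 - 1.0)
            extra = rng.normal(0.0, extra_sd, size=int(in_parcel.sum()))
            img[in_parcel] += extra - extra.mean()
    return ScalarImage(np.clip(img, 0.0, 1.0), envelope.affine)


@dataclass
class CohortSubject:
    subject_id: str
    tractogram: Tractogram
    image: ScalarImage
    group: str


def make_cohort(
    cohort: CohortSpec, phantom: PhantomSpec
) -> Tuple[List[CohortSubject], BinaryMask, BinaryMask, LabelImage]:
    """Balanced two-group cohort of per-subject bundles and images.

    All subjects share the phantom's envelope, start ROI and ground-truth
    parcel geometry (the cohort emulates perfectly co-registered data);
    streamline jitter and image noise are per-subject.  Returns
    ``(subjects, envelope, start_roi, ground_truth)``.
    """
    base = PhantomSpec(**{**phantom.__dict__, "seed": phantom.seed})
    tract, envelope, start_roi, _ = make_bundle(base)
    gt = ground_truth_parcels(tract, envelope, cohort.n_parcels)
    rng = np.random.default_rng(cohort.seed)
    subjects = []
    for i in range(2 * cohort.n_per_group):
        group = "A" if i < cohort.n_per_group else "B"
        sub_spec = PhantomSpec(
            **{**phantom.__dict__, "seed": int(rng.integers(0, 2**31 - 1))}
        )
        sub_tract = make_streamlines(sub_spec)
        img = make_subject_image(
            envelope, gt, group, cohort, subject_seed=int(rng.integers(0, 2**31 - 1))
        )
        subjects.append(CohortSubject(f"sub-{i:03d}", sub_tract, img, group))
    return subjects, envelope, start_roi, gt
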