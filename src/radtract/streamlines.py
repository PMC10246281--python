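"""Streamline geometry: resampling, orientation alignment, MDF distance,
centerlines, clustering-based reduction and traversed-voxel counting.

The minimum average direct-flip (MDF) distance between two equally
resampled streamlines is the mean pointwise Euclidean distance, minimized
over reversing one of them.  It drives both orientation alignment and the
single-pass clustering used to thin dense bundles before parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .core_io import (
    BinaryMask,
    EmptyInputError,
    ScalarImage,
    Streamline,
    Tractogram,
    nearest_voxel,
    voxel_centers,
    world_to_index,
)

#: number of points streamlines are resampled to when computing MDF for
#: clustering and orientation; a coarse polyline is enough for bundle-level
#: geometry and keeps clustering cheap
DEFAULT_MDF_POINTS = 12


@dataclass
class Centerline:
    """Single representative polyline for a bundle (world mm)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centerline must be an (n>=2, 3) array")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class ClusterSet:
    """Result of streamline clustering: a partition plus representatives."""

    clusters: List[List[int]]
    representatives: List[np.ndarray]
    threshold: float


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal arc-length spacing."""
    if n < 2:
        raise ValueError("need n >= 2 points")
    points = np.asarray(points, dtype=float)
    arc = _arc_lengths(points)
    total = arc[-1]
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for axis in range(3):
        out[:, axis] = np.interp(targets, arc, points[:, axis])
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def resample_streamline(s: Streamline, n: int) -> Streamline:
    """Arc-length resampling preserving the exact endpoints."""
    return Streamline(resample_polyline(s.points, n), id=s.id)


def mdf_distance(
    a: Streamline | np.ndarray,
    b: Streamline | np.ndarray,
    n: int = DEFAULT_MDF_POINTS,
) -> Tuple[float, bool]:
    """Minimum average direct-flip distance between two streamlines.

    Returns ``(distance_mm, flipped)`` where ``flipped`` is True when the
    minimum was attained with ``b`` reversed.
    """
    pa = a.points if isinstance(a, Streamline) else np.asarray(a, dtype=float)
    pb = b.points if isinstance(b, Streamline) else np.asarray(b, dtype=float)
    ra = resample_polyline(pa, n)
    rb = resample_polyline(pb, n)
    direct = float(np.mean(np.linalg.norm(ra - rb, axis=1)))
    flipped = float(np.mean(np.linalg.norm(ra - rb[::-1], axis=1)))
    if flipped < direct:
        return flipped, True
    return direct, False


def orient_by_start_roi(t: Tractogram, roi: BinaryMask) -> Tractogram:
    """Reverse streamlines whose last point is closer to the start ROI.

    Distance is to the nearest nonzero ROI voxel center; ties keep the
    input point order, which makes the operation idempotent.
    """
    centers = voxel_centers(roi)  # raises EmptyInputError for empty ROI
    out = []
    for s in t.streamlines:
        d_first = np.min(np.linalg.norm(centers - s.points[0], axis=1))
        d_last = np.min(np.linalg.norm(centers - s.points[-1], axis=1))
        out.append(s.reversed() if d_last < d_first else s)
    return t.with_streamlines(out)


def orient_by_centerline(
    t: Tractogram, c: Centerline, n: int = DEFAULT_MDF_POINTS
) -> Tractogram:
    """Reverse streamlines flipped in terms of MDF to the centerline."""
    out = []
    for s in t.streamlines:
        _, flipped = mdf_distance(s, c.points, n=n)
        out.append(s.reversed() if flipped else s)
    return t.with_streamlines(out)


def compute_centerline(t: Tractogram, n: int) -> Centerline:
    """Pointwise mean of all streamlines resampled to ``n`` points.

    Assumes the tractogram is orientation-aligned.
    """
    if len(t) == 0:
        raise EmptyInputError("empty tractogram")
    stack = np.stack([resample_polyline(s.points, n) for s in t.streamlines])
    return Centerline(stack.mean(axis=0))


# ---------------------------------------------------------------------------
# Clustering-based reduction (QuickBundles scheme)


def _mdf_to_centroid(centroid: np.ndarray, pts: np.ndarray) -> Tuple[float, bool]:
    direct = float(np.mean(np.linalg.norm(centroid - pts, axis=1)))
    flipped = float(np.mean(np.linalg.norm(centroid - pts[::-1], axis=1)))
    return (flipped, True) if flipped < direct else (direct, False)


def quickbundles(
    resampled: np.ndarray, threshold: float
) -> Tuple[List[List[int]], List[np.ndarray]]:
    """Single-pass clustering of pre-resampled streamlines.

    Each streamline joins the cluster whose running-mean centroid is
    within ``threshold`` MDF, flipping its orientation to match the
    centroid if that attains the minimum; otherwise it seeds a new
    cluster.  Deterministic in the input order.
    """
    clusters: List[List[int]] = []
    sums: List[np.ndarray] = []
    centroids: List[np.ndarray] = []
    for i, pts in enumerate(resampled):
        best_j, best_d, best_flip = -1, np.inf, False
        for j, c in enumerate(centroids):
            d, flip = _mdf_to_centroid(c, pts)
            if d < best_d:
                best_j, best_d, best_flip = j, d, flip
        if best_j >= 0 and best_d <= threshold:
            add = pts[::-1] if best_flip else pts
            clusters[best_j].append(i)
            sums[best_j] = sums[best_j] + add
            centroids[best_j] = sums[best_j] / len(clusters[best_j])
        else:
            clusters.append([i])
            sums.append(pts.copy())
            centroids.append(pts.copy())
    return clusters, centroids


def reduce_streamlines(
    t: Tractogram,
    target: int = 500,
    seed: int = 0,
    n_points: int = DEFAULT_MDF_POINTS,
    band: float = 0.1,
) -> Tractogram:
    """Thin a dense bundle to about ``target`` streamlines.

    Streamlines are clustered by MDF against running-mean centroids at a
    distance threshold found by bisection so the cluster count lands
    within ``band`` (default +/-10%) of ``target``; the centroids become
    the reduced bundle.  If no threshold reaches the band (e.g. many
    exactly coincident streamlines), falls back to seeded uniform
    subsampling to exactly ``target``.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    if len(t) <= target:
        return t
    resampled = np.stack([resample_polyline(s.points, n_points) for s in t.streamlines])
    lo_count, hi_count = int(np.floor(target * (1 - band))), int(
        np.ceil(target * (1 + band))
    )
    # threshold bounds: 0 -> every streamline its own cluster; bundle radius
    # -> one cluster.  Bisection on the (monotonically non-increasing)
    # cluster count.
    extent = float(np.linalg.norm(resampled.max(axis=(0, 1)) - resampled.min(axis=(0, 1))))
    lo_t, hi_t = 0.0, max(extent, 1e-6)
    best = None
    for _ in range(40):
        mid = 0.5 * (lo_t + hi_t)
        clusters, centroids = quickbundles(resampled, mid)
        count = len(clusters)
        if lo_count <= count <= hi_count:
            best = centroids
            break
        if count > hi_count:
            lo_t = mid  # too many clusters -> need larger threshold
        else:
            hi_t = mid
    if best is None:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(t), size=target, replace=False))
        return t.with_streamlines([t.streamlines[i] for i in keep])
    return t.with_streamlines(
        [Streamline(c, id=i) for i, c in enumerate(best)]
    )


# ---------------------------------------------------------------------------
# Voxel traversal


def traversed_voxels(s: Streamline, grid: ScalarImage) -> np.ndarray:
    """Unique voxel indices visited by walking the polyline.

    The polyline is walked at a step of half the minimum voxel size;
    points falling outside the grid are ignored.
    """
    step = 0.5 * float(min(grid.voxel_sizes))
    arc = _arc_lengths(s.points)
    total = arc[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    dense = resample_polyline(s.points, n)
    idx = nearest_voxel(world_to_index(grid, dense))
    shape = np.asarray(grid.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    idx = idx[inside]
    if len(idx) == 0:
        return np.empty((0, 3), dtype=np.int64)
    return np.unique(idx, axis=0)


def count_traversed_voxels(s: Streamline, grid: ScalarImage) -> int:
    """Number of unique voxels a streamline passes through."""
    return len(traversed_voxels(s, grid))
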