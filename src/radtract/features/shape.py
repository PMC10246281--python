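"""3-D shape descriptors of a binary parcel.

Mesh-based quantities (volume, surface area, sphericity, diameters) use
a marching-cubes surface of the zero-padded binary parcel in physical
coordinates; axis lengths come from the principal components of the
voxel-center point cloud, scaled by 4 so a solid ellipsoid recovers its
semi-axes times two.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from skimage import measure

from .registry import SHAPE_FEATURES

_MAX_DIAMETER_VERTICES = 2000


def _max_pairwise(points: np.ndarray, rng_seed: int = 0) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > _MAX_DIAMETER_VERTICES:
        rng = np.random.default_rng(rng_seed)
        points = points[rng.choice(len(points), _MAX_DIAMETER_VERTICES, replace=False)]
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.sum(np.einsum("ij,ij->i", v0, np.cross(v1, v2)))) / 6.0)


def compute_shape(mask: np.ndarray, spacing: np.ndarray) -> Dict[str, float]:
    """The 14 shape features of a binary voxel region.

    ``mask`` is a boolean array (any enclosing grid); ``spacing`` the
    voxel sizes in mm.  Intensities play no role.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    n_voxels = int(mask.sum())
    if n_voxels == 0:
        raise ValueError("empty parcel")
    voxel_volume = float(np.prod(spacing))

    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded.astype(float), level=0.5, spacing=tuple(spacing)
    )
    area = float(measure.mesh_surface_area(verts, faces))
    mesh_volume = _mesh_volume(verts, faces)
    surface_volume_ratio = area / mesh_volume if mesh_volume > 0 else 0.0
    sphericity = (
        (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / area if area > 0 else 0.0
    )

    coords = (np.argwhere(mask) * spacing).astype(float)
    if n_voxels >= 2:
        cov = np.cov(coords, rowvar=False)
        eigvals = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))[::-1]
        major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
        elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 0.0
        flatness = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 0.0
    else:
        # single voxel: surrogate axes from the voxel box itself
        major, minor, least = np.sort(spacing)[::-1].tolist()
        elongation = minor / major
        flatness = least / major

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n_voxels * voxel_volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": surface_volume_ratio,
        "Sphericity": sphericity,
        "Maximum3DDiameter": _max_pairwise(verts),
        "Maximum2DDiameterSlice": _max_pairwise(verts[:, :2]),
        "Maximum2DDiameterColumn": _max_pairwise(verts[:, [0, 2]]),
        "Maximum2DDiameterRow": _max_pairwise(verts[:, 1:]),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }


assert tuple(compute_shape(np.ones((2, 2, 2)), np.ones(3)).keys()) == SHAPE_FEATURES
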