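"""Core data model and file IO.

Streamlines live in world millimetre coordinates (RAS); images are voxel
grids tied to a 4x4 affine mapping 0-based voxel indices to world
coordinates, with voxel centers at integer indices.  Tractography dialects
that store voxel-scaled or corner-based coordinates are normalized to this
convention on load, so every downstream operation can assume a single
world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence

import nibabel as nib
import numpy as np
from nibabel import streamlines as nib_streamlines


class FormatError(ValueError):
    """File could not be parsed as the expected format."""


class EmptyInputError(ValueError):
    """An operation received an input with no usable content."""


# ---------------------------------------------------------------------------
# Streamlines and tractograms


@dataclass
class Streamline:
    """Ordered 3-D polyline in world millimetre coordinates."""

    points: np.ndarray  # (k, 3) float
    id: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("streamline points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("streamline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("streamline coordinates must be finite")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive streamline points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    def reversed(self) -> "Streamline":
        return Streamline(self.points[::-1].copy(), id=self.id)


@dataclass
class GridReference:
    """Voxel grid descriptor: shape, voxel sizes (mm) and index->world affine."""

    shape: tuple
    affine: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class Tractogram:
    """Bundle of streamlines sharing one world frame and reference grid."""

    streamlines: List[Streamline]
    reference: GridReference

    def __post_init__(self) -> None:
        self.streamlines = list(self.streamlines)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[Streamline]:
        return iter(self.streamlines)

    def with_streamlines(self, streamlines: Iterable[Streamline]) -> "Tractogram":
        return Tractogram(list(streamlines), self.reference)


# ---------------------------------------------------------------------------
# Images


@dataclass
class ScalarImage:
    """3-D scalar volume with an index->world affine."""

    voxels: np.ndarray
    affine: np.ndarray

    _expected_dtype = float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=self._expected_dtype)
        if self.voxels.ndim != 3:
            raise ValueError("image must be 3-D")
        if min(self.voxels.shape) < 1:
            raise ValueError("image shape must be >= 1 along every axis")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        self._validate()

    def _validate(self) -> None:
        pass

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def reference(self) -> GridReference:
        return GridReference(self.voxels.shape, self.affine)


@dataclass
class BinaryMask(ScalarImage):
    """Binary {0,1} volume, e.g. a tract envelope or start-region ROI."""

    _expected_dtype = np.uint8

    def _validate(self) -> None:
        values = np.unique(self.voxels)
        if not np.all(np.isin(values, (0, 1))):
            raise ValueError("mask voxels must be 0 or 1")

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class LabelImage(ScalarImage):
    """Integer label volume; 0 is background, 1..n are parcels."""

    _expected_dtype = np.int32

    def _validate(self) -> None:
        if self.voxels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n(self) -> int:
        return int(self.voxels.max())


# ---------------------------------------------------------------------------
# Coordinate transforms


def world_to_index(image: ScalarImage | GridReference, points: np.ndarray) -> np.ndarray:
    """Map world mm coordinates to continuous 0-based voxel indices."""
    affine = image.affine
    inv = np.linalg.inv(affine)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts @ inv[:3, :3].T + inv[:3, 3]
    return out if np.asarray(points).ndim == 2 else out[0]


def index_to_world(image: ScalarImage | GridReference, indices: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices to world mm coordinates."""
    affine = image.affine
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    out = idx @ affine[:3, :3].T + affine[:3, 3]
    return out if np.asarray(indices).ndim == 2 else out[0]


def nearest_voxel(indices: np.ndarray) -> np.ndarray:
    """Round continuous indices to voxel indices; ties go to the lower index."""
    return np.ceil(np.asarray(indices, dtype=float) - 0.5).astype(np.int64)


def voxel_centers(mask: BinaryMask) -> np.ndarray:
    """World coordinates of the centers of all nonzero voxels.

    Order is deterministic: lexicographic in voxel index.
    """
    idx = np.argwhere(mask.voxels > 0)
    if len(idx) == 0:
        raise EmptyInputError("mask has no nonzero voxels")
    return index_to_world(mask, idx.astype(float))


# ---------------------------------------------------------------------------
# File IO


def read_image(path: str | Path, kind: str = "scalar") -> ScalarImage:
    """Read a NIfTI volume as a ScalarImage, BinaryMask or LabelImage.

    Parameters
    ----------
    kind : {"scalar", "mask", "label"}
        Validation applied to the voxel data.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got shape {data.shape}")
    affine = img.affine
    if kind == "scalar":
        return ScalarImage(data.astype(float), affine)
    if kind == "mask":
        return BinaryMask(data, affine)
    if kind == "label":
        if not np.allclose(data, np.round(data)):
            raise ValueError("label image voxels must be integers")
        return LabelImage(np.round(data).astype(np.int32), affine)
    raise ValueError(f"unknown image kind {kind!r}")


def write_image(image: ScalarImage, path: str | Path) -> None:
    data = image.voxels
    if isinstance(image, BinaryMask):
        data = data.astype(np.uint8)
    elif isinstance(image, LabelImage):
        data = data.astype(np.int32)
    nib.save(nib.Nifti1Image(data, image.affine), str(path))


def _reference_from_header(tfile) -> GridReference:
    header = tfile.header
    affine = np.asarray(tfile.affine if hasattr(tfile, "affine") else np.eye(4))
    dims = header.get("dimensions")
    affine_key = "voxel_to_rasmm"
    if affine_key in header and np.asarray(header[affine_key]).shape == (4, 4):
        affine = np.asarray(header[affine_key], dtype=float)
    if dims is None:
        dims = (1, 1, 1)
    if abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
        affine = np.eye(4)
    return GridReference(tuple(int(d) for d in dims), affine)


def read_tractogram(path: str | Path) -> Tractogram:
    """Read a TRK/TCK tractogram; streamlines come back in world mm (RAS)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tfile = nib_streamlines.load(str(path))
    except Exception as exc:  # nibabel raises several header/format errors
        raise FormatError(f"could not read tractogram {path}: {exc}") from exc
    # nibabel returns streamlines already transformed to RAS mm
    sls = [np.asarray(s, dtype=float) for s in tfile.streamlines]
    sls = [s for s in sls if len(s) >= 2]
    if not sls:
        raise EmptyInputError(f"tractogram {path} contains no streamlines")
    reference = _reference_from_header(tfile)
    return Tractogram(
        [Streamline(_dedupe_consecutive(s), id=i) for i, s in enumerate(sls)],
        reference,
    )


def _dedupe_consecutive(points: np.ndarray) -> np.ndarray:
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(np.diff(points, axis=0) != 0, axis=1)
    return points[keep]


def write_tractogram(t: Tractogram, path: str | Path) -> None:
    """Write TRK or TCK (by extension); input coordinates are world mm."""
    path = Path(path)
    sl = nib_streamlines.Tractogram(
        [s.points for s in t.streamlines], affine_to_rasmm=np.eye(4)
    )
    if path.suffix == ".trk":
        header = {
            "voxel_to_rasmm": t.reference.affine.astype(np.float32),
            "voxel_sizes": t.reference.voxel_sizes.astype(np.float32),
            "dimensions": np.asarray(t.reference.shape, dtype=np.int16),
            "voxel_order": "".join(nib.aff2axcodes(t.reference.affine)),
        }
        nib_streamlines.save(sl, str(path), header=header)
    elif path.suffix == ".tck":
        nib_streamlines.save(sl, str(path))
    else:
        raise FormatError(f"unsupported tractogram extension {path.suffix!r}")
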