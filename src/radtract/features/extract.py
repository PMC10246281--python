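"""Per-parcel feature extraction and the classic tract-profile baseline.

For each parcel of a label image the engine computes shape features on
the original geometry plus first-order and texture features on the
original image and on every image of the filter bank.  With the default
bank (3 LoG + 8 wavelet bands) this yields 105 features on the original
image and 91 per filtered image — 1106 per parcel.

Column names follow ``<filter>_<family>_<feature>``, e.g.
``original_firstorder_Mean`` or ``wavelet-LLH_glcm_Contrast``, and are
stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from ..core_io import EmptyInputError, LabelImage, ScalarImage, Tractogram
from ..streamlines import compute_centerline
from .filters import DEFAULT_LOG_SIGMAS, DEFAULT_WAVELET, apply_filter_bank
from .firstorder import compute_first_order, discretize
from .registry import FAMILY_FEATURES, INTENSITY_FAMILIES
from .shape import compute_shape
from .texture import compute_texture_family

#: the named feature subsets used for ablation: a family across all
#: images, a filter class across all families, or the first-order
#: features of the unfiltered image alone
SUBSETS = (
    "all",
    "firstorder",
    "shape",
    "glcm",
    "glrlm",
    "glszm",
    "gldm",
    "ngtdm",
    "original",
    "log",
    "wavelet",
    "firstorder-original",
)


@dataclass
class FeatureConfig:
    """Extraction settings: families, filter bank and discretization."""

    families: Tuple[str, ...] = ("shape",) + INTENSITY_FAMILIES
    log_sigmas: Tuple[float, ...] = DEFAULT_LOG_SIGMAS
    wavelet: str = DEFAULT_WAVELET
    use_filters: bool = True
    n_bins: int = 32
    bin_width: float | None = None
    subset_name: str = "all"

    def __post_init__(self) -> None:
        if self.subset_name not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset_name!r}")
        for fam in self.families:
            if fam not in FAMILY_FEATURES:
                raise ValueError(f"unknown family {fam!r}")


def column_in_subset(column: str, subset: str) -> bool:
    """Whether a ``filter_family_feature`` column belongs to a subset."""
    filt, family, _ = column.split("_", 2)
    if subset == "all":
        return True
    if subset == "original":
        return filt == "original"
    if subset == "log":
        return filt.startswith("log-")
    if subset == "wavelet":
        return filt.startswith("wavelet-")
    if subset == "firstorder-original":
        return filt == "original" and family == "firstorder"
    return family == subset


def _parcel_features(
    bank: Dict[str, ScalarImage],
    parcel_mask: np.ndarray,
    spacing: np.ndarray,
    config: FeatureConfig,
) -> Dict[str, float]:
    out: Dict[str, float] = {}
    voxel_volume = float(np.prod(spacing))
    n_voxels = int(parcel_mask.sum())
    if "shape" in config.families:
        if n_voxels:
            shape_vals = compute_shape(parcel_mask, spacing)
        else:
            shape_vals = {k: np.nan for k in FAMILY_FEATURES["shape"]}
        for k, v in shape_vals.items():
            out[f"original_shape_{k}"] = v
    texture_families = [f for f in config.families if f in INTENSITY_FAMILIES and f != "firstorder"]
    for filt, img in bank.items():
        values = img.voxels[parcel_mask] if n_voxels else np.empty(0)
        degenerate = n_voxels == 0
        if not degenerate:
            labels = discretize(values, n_bins=config.n_bins, bin_width=config.bin_width)
        if "firstorder" in config.families:
            fo = (
                compute_first_order(
                    values, voxel_volume=voxel_volume, discretized=labels
                )
                if not degenerate
                else {k: np.nan for k in FAMILY_FEATURES["firstorder"]}
            )
            for k, v in fo.items():
                out[f"{filt}_firstorder_{k}"] = v
        if texture_families and not degenerate:
            level_img = np.zeros(parcel_mask.shape, dtype=np.int64)
            level_img[parcel_mask] = labels
        for fam in texture_families:
            vals = (
                compute_texture_family(fam, level_img)
                if not degenerate
                else {k: np.nan for k in FAMILY_FEATURES[fam]}
            )
            for k, v in vals.items():
                out[f"{filt}_{fam}_{k}"] = v
    return out


def extract_features_per_parcel(
    img: ScalarImage,
    parcels: LabelImage,
    config: FeatureConfig | None = None,
    n_parcels: int | None = None,
) -> pd.DataFrame:
    """Feature table for every parcel of a label image.

    Returns a wide DataFrame indexed by parcel label 1..n with one column
    per registry feature.  Parcels absent from the label image yield a
    row of NaN (flagged, never silently dropped).
    """
    config = config or FeatureConfig()
    if img.shape != parcels.shape:
        raise ValueError("image and parcel label image must share a grid")
    n = n_parcels or parcels.n
    if n < 1:
        raise EmptyInputError("label image contains no parcels")
    bank = (
        apply_filter_bank(img, log_sigmas=config.log_sigmas, wavelet=config.wavelet)
        if config.use_filters
        else {"original": img}
    )
    spacing = img.voxel_sizes
    rows = []
    for k in range(1, n + 1):
        parcel_mask = parcels.voxels == k
        feats = _parcel_features(bank, parcel_mask, spacing, config)
        feats["parcel"] = k
        rows.append(feats)
    table = pd.DataFrame(rows).set_index("parcel")
    if config.subset_name != "all":
        keep = [c for c in table.columns if column_in_subset(c, config.subset_name)]
        table = table[keep]
    return table


def table_to_long(
    table: pd.DataFrame, subject: str = "subject", tract: str = "tract"
) -> pd.DataFrame:
    """Wide per-parcel table -> long `subject,tract,parcel,feature,value`."""
    long = table.reset_index().melt(
        id_vars="parcel", var_name="feature", value_name="value"
    )
    long.insert(0, "tract", tract)
    long.insert(0, "subject", subject)
    return long


def long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Long schema -> one row per (subject, tract), parcel-tagged columns."""
    wide = long.pivot_table(
        index=["subject", "tract"],
        columns=["parcel", "feature"],
        values="value",
        aggfunc="first",
    )
    wide.columns = [f"p{p}_{f}" for p, f in wide.columns]
    return wide


def subject_feature_vector(table: pd.DataFrame) -> pd.Series:
    """Flatten a per-parcel table to one vector with p<parcel>_ prefixes."""
    parts = {}
    for parcel, row in table.iterrows():
        for col, val in row.items():
            parts[f"p{parcel}_{col}"] = val
    return pd.Series(parts)


# ---------------------------------------------------------------------------
# Classic tract profile


def classic_tract_profile(
    img: ScalarImage,
    t: Tractogram,
    n_profile: int = 100,
) -> np.ndarray:
    """Centerline-assignment tract profile of ``n_profile`` means.

    The image is sampled trilinearly at every streamline point; each
    sample is assigned to the nearest of ``n_profile`` centerline points
    and per-bin means are returned (NaN for empty bins).  The tract must
    be orientation-aligned.
    """
    if len(t) == 0:
        raise EmptyInputError("empty tractogram")
    centerline = compute_centerline(t, n_profile)
    points = np.concatenate([s.points for s in t.streamlines])
    from ..core_io import world_to_index

    idx = world_to_index(img, points)
    samples = ndimage.map_coordinates(
        img.voxels.astype(float), idx.T, order=1, mode="nearest"
    )
    d = np.linalg.norm(points[:, None, :] - centerline.points[None, :, :], axis=2)
    assign = d.argmin(axis=1)
    profile = np.full(n_profile, np.nan)
    for k in range(n_profile):
        sel = assign == k
        if sel.any():
            profile[k] = samples[sel].mean()
    return profile
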