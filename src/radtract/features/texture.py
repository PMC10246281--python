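"""Gray-level texture matrix families on 3-D masked regions.

Five families computed from a discretized region (integer levels 1..B
inside the mask, 0 outside):

* GLCM  — co-occurrence of level pairs at the 13 unique 26-connected
  offsets; features averaged over directions.
* GLRLM — maximal runs of equal level along each of the 13 directions;
  features averaged over directions.
* GLSZM — 26-connected zones of equal level (direction-free).
* GLDM  — per-voxel dependence: 1 + number of 26-neighbors inside the
  mask with the same level.
* NGTDM — per-level summed deviation from the mean of the valid
  26-neighborhood.

All derived statistics use the gray-level *values* (bin labels), so
constant regions give zero contrast by construction.  A small epsilon
guards the logarithms.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .registry import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
)

_EPS = np.finfo(float).eps

#: the 13 unique direction offsets of the 26-neighborhood (first nonzero
#: component positive)
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _crop_to_mask(levels: np.ndarray) -> np.ndarray:
    """Bounding-box crop with a 1-voxel margin of zeros."""
    idx = np.argwhere(levels > 0)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = levels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    return np.pad(sub, 1)


def _offset_views(a: np.ndarray, d: Tuple[int, int, int]):
    """Views of ``a`` shifted by +d: (base, shifted) aligned element-wise."""
    sl_a, sl_b = [], []
    for k, dk in enumerate(d):
        n = a.shape[k]
        if dk == 0:
            sl_a.append(slice(0, n))
            sl_b.append(slice(0, n))
        elif dk > 0:
            sl_a.append(slice(0, n - dk))
            sl_b.append(slice(dk, n))
        else:
            sl_a.append(slice(-dk, n))
            sl_b.append(slice(0, n + dk))
    return a[tuple(sl_a)], a[tuple(sl_b)]


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(levels: np.ndarray, direction: Tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts P[i-1, j-1] for one direction."""
    n = int(levels.max())
    a, b = _offset_views(levels, direction)
    valid = (a > 0) & (b > 0)
    i, j = a[valid], b[valid]
    P = np.zeros((n, n))
    np.add.at(P, (i - 1, j - 1), 1)
    return P + P.T


def _glcm_features_single(P: np.ndarray) -> Dict[str, float]:
    s = P.sum()
    if s == 0:
        return {k: 0.0 for k in GLCM_FEATURES}
    p = P / s
    n = P.shape[0]
    lv = np.arange(1, n + 1, dtype=float)
    I, J = np.meshgrid(lv, lv, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((lv * px).sum())
    uy = float((lv * py).sum())
    sx = np.sqrt(float(((lv - ux) ** 2 * px).sum()))
    sy = np.sqrt(float(((lv - uy) ** 2 * py).sum()))

    ksum = np.arange(2, 2 * n + 1, dtype=float)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (I + J).astype(int).ravel() - 2, p.ravel())
    kdiff = np.arange(0, n, dtype=float)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), p.ravel())

    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    hxy = float(-np.sum(p[p > 0] * np.log2(p[p > 0])))
    pxpy = np.outer(px, py)
    hxy1 = float(-np.sum(p * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy[pxpy > 0] * np.log2(pxpy[pxpy > 0])))

    diff_avg = float((kdiff * p_diff).sum())
    denom = sx * sy
    if denom > 0:
        correlation = float(((I * J * p).sum() - ux * uy) / denom)
    else:
        correlation = 1.0
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off = I != J

    return {
        "Autocorrelation": float((I * J * p).sum()),
        "JointAverage": ux,
        "ClusterProminence": float((((I + J - ux - uy) ** 4) * p).sum()),
        "ClusterShade": float((((I + J - ux - uy) ** 3) * p).sum()),
        "ClusterTendency": float((((I + J - ux - uy) ** 2) * p).sum()),
        "Contrast": float((((I - J) ** 2) * p).sum()),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(
            -np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0]))
        ),
        "DifferenceVariance": float(((kdiff - diff_avg) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((I - J) ** 2) / n**2)).sum()),
        "Id": float((p / (1.0 + np.abs(I - J))).sum()),
        "Idn": float((p / (1.0 + np.abs(I - J) / n)).sum()),
        "InverseVariance": float((p[off] / (I[off] - J[off]) ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0]))),
        "SumSquares": float((((I - ux) ** 2) * p).sum()),
    }


def compute_glcm(levels: np.ndarray) -> Dict[str, float]:
    """GLCM features averaged over the 13 unique 3-D directions."""
    levels = _crop_to_mask(levels)
    acc = {k: 0.0 for k in GLCM_FEATURES}
    for d in DIRECTIONS_13:
        f = _glcm_features_single(glcm_matrix(levels, d))
        for k, v in f.items():
            acc[k] += v
    return {k: v / len(DIRECTIONS_13) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(levels: np.ndarray, direction: Tuple[int, int, int]) -> np.ndarray:
    """Run-length counts P[i-1, r-1] along one direction.

    Maximal runs of equal gray level are the connected components of each
    level set under connectivity restricted to +/- the direction.
    """
    n = int(levels.max())
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1, 1, 1] = True
    structure[1 + direction[0], 1 + direction[1], 1 + direction[2]] = True
    structure[1 - direction[0], 1 - direction[1], 1 - direction[2]] = True
    max_run = max(levels.shape)
    P = np.zeros((n, max_run))
    for lev in np.unique(levels[levels > 0]):
        lab, n_runs = ndimage.label(levels == lev, structure=structure)
        if n_runs == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        hist = np.bincount(sizes, minlength=max_run + 1)[1 : max_run + 1]
        P[lev - 1, : len(hist)] += hist
    return P


def _run_type_features(P: np.ndarray, n_voxels: int, kind: str) -> Dict[str, float]:
    """Shared feature formulas of the run-length / size-zone families."""
    Nr = P.sum()
    names = GLRLM_FEATURES if kind == "run" else GLSZM_FEATURES
    if Nr == 0:
        return {k: 0.0 for k in names}
    n_levels, n_sizes = P.shape
    iv = np.arange(1, n_levels + 1, dtype=float)
    jv = np.arange(1, n_sizes + 1, dtype=float)
    I, J = np.meshgrid(iv, jv, indexing="ij")
    p = P / Nr
    gray_sum = P.sum(axis=1)
    size_sum = P.sum(axis=0)
    mu_i = float((I * p).sum())
    mu_j = float((J * p).sum())
    pr = p[p > 0]
    vals = {
        "Short": float((P / J**2).sum() / Nr),
        "Long": float((P * J**2).sum() / Nr),
        "GrayLevelNonUniformity": float((gray_sum**2).sum() / Nr),
        "GrayLevelNonUniformityNormalized": float((gray_sum**2).sum() / Nr**2),
        "SizeNonUniformity": float((size_sum**2).sum() / Nr),
        "SizeNonUniformityNormalized": float((size_sum**2).sum() / Nr**2),
        "Percentage": float(Nr / n_voxels),
        "GrayLevelVariance": float((((I - mu_i) ** 2) * p).sum()),
        "SizeVariance": float((((J - mu_j) ** 2) * p).sum()),
        "Entropy": float(-np.sum(pr * np.log2(pr))),
        "LowGray": float((P / I**2).sum() / Nr),
        "HighGray": float((P * I**2).sum() / Nr),
        "ShortLowGray": float((P / (I**2 * J**2)).sum() / Nr),
        "ShortHighGray": float((P * I**2 / J**2).sum() / Nr),
        "LongLowGray": float((P * J**2 / I**2).sum() / Nr),
        "LongHighGray": float((P * I**2 * J**2).sum() / Nr),
    }
    order = (
        "Short",
        "Long",
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "SizeNonUniformity",
        "SizeNonUniformityNormalized",
        "Percentage",
        "GrayLevelVariance",
        "SizeVariance",
        "Entropy",
        "LowGray",
        "HighGray",
        "ShortLowGray",
        "ShortHighGray",
        "LongLowGray",
        "LongHighGray",
    )
    return dict(zip(names, (vals[k] for k in order)))


def compute_glrlm(levels: np.ndarray) -> Dict[str, float]:
    """GLRLM features averaged over the 13 unique 3-D directions."""
    levels = _crop_to_mask(levels)
    n_voxels = int((levels > 0).sum())
    acc = {k: 0.0 for k in GLRLM_FEATURES}
    for d in DIRECTIONS_13:
        f = _run_type_features(glrlm_matrix(levels, d), n_voxels, kind="run")
        for k, v in f.items():
            acc[k] += v
    return {k: v / len(DIRECTIONS_13) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(levels: np.ndarray) -> np.ndarray:
    """Zone-size counts P[i-1, s-1] over 26-connected equal-level zones."""
    n = int(levels.max())
    max_size = int((levels > 0).sum())
    P = np.zeros((n, max_size))
    for lev in np.unique(levels[levels > 0]):
        lab, n_zones = ndimage.label(levels == lev, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        hist = np.bincount(sizes, minlength=max_size + 1)[1 : max_size + 1]
        P[lev - 1] += hist
    return P


def compute_glszm(levels: np.ndarray) -> Dict[str, float]:
    levels = _crop_to_mask(levels)
    n_voxels = int((levels > 0).sum())
    return _run_type_features(glszm_matrix(levels), n_voxels, kind="zone")


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence counts P[i-1, d-1], d = 1 + #similar 26-neighbors."""
    n = int(levels.max())
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        a, b = _offset_views(levels, d)
        ok = (a > 0) & (b > 0) & (np.abs(a.astype(int) - b.astype(int)) <= alpha)
        da, db = _offset_views(dep, d)
        da += ok
        db += ok
    P = np.zeros((n, 27))
    i = levels[mask]
    j = dep[mask]
    np.add.at(P, (i - 1, j), 1)
    return P


def compute_gldm(levels: np.ndarray, alpha: int = 0) -> Dict[str, float]:
    levels = _crop_to_mask(levels)
    P = gldm_matrix(levels, alpha=alpha)
    Nz = P.sum()
    if Nz == 0:
        return {k: 0.0 for k in GLDM_FEATURES}
    n_levels, n_dep = P.shape
    iv = np.arange(1, n_levels + 1, dtype=float)
    jv = np.arange(1, n_dep + 1, dtype=float)
    I, J = np.meshgrid(iv, jv, indexing="ij")
    p = P / Nz
    gray_sum = P.sum(axis=1)
    dep_sum = P.sum(axis=0)
    mu_i = float((I * p).sum())
    mu_j = float((J * p).sum())
    pr = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((P / J**2).sum() / Nz),
        "LargeDependenceEmphasis": float((P * J**2).sum() / Nz),
        "GrayLevelNonUniformity": float((gray_sum**2).sum() / Nz),
        "DependenceNonUniformity": float((dep_sum**2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((dep_sum**2).sum() / Nz**2),
        "GrayLevelVariance": float((((I - mu_i) ** 2) * p).sum()),
        "DependenceVariance": float((((J - mu_j) ** 2) * p).sum()),
        "DependenceEntropy": float(-np.sum(pr * np.log2(pr))),
        "LowGrayLevelEmphasis": float((P / I**2).sum() / Nz),
        "HighGrayLevelEmphasis": float((P * I**2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (I**2 * J**2)).sum() / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * I**2 / J**2).sum() / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * J**2 / I**2).sum() / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * I**2 * J**2).sum() / Nz),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(levels: np.ndarray) -> Tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_i, s_i) of the neighbouring gray-tone difference matrix.

    s_i sums |i - A| over voxels of level i, where A is the mean level of
    the voxel's in-mask 26-neighbors; voxels with no in-mask neighbor are
    excluded.  Returns (counts, s, n_valid_voxels).
    """
    n = int(levels.max())
    mask = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        a, b = _offset_views(levels, d)
        ok = (a > 0) & (b > 0)
        sa, sb = _offset_views(nb_sum, d)
        ca, cb = _offset_views(nb_cnt, d)
        sa += np.where(ok, b, 0)
        sb += np.where(ok, a, 0)
        ca += ok
        cb += ok
    valid = mask & (nb_cnt > 0)
    A = np.zeros(levels.shape)
    A[valid] = nb_sum[valid] / nb_cnt[valid]
    counts = np.zeros(n)
    s = np.zeros(n)
    i = levels[valid]
    np.add.at(counts, i - 1, 1)
    np.add.at(s, i - 1, np.abs(i - A[valid]))
    return counts, s, int(valid.sum())


def compute_ngtdm(levels: np.ndarray) -> Dict[str, float]:
    levels = _crop_to_mask(levels)
    counts, s, n_valid = ngtdm_table(levels)
    if n_valid == 0:
        return {k: 0.0 for k in NGTDM_FEATURES}
    p = counts / n_valid
    nz = p > 0
    iv = np.arange(1, len(p) + 1, dtype=float)
    ngp = int(nz.sum())
    pi, ii, si = p[nz], iv[nz], s[nz]

    coarse_denom = float((pi * si).sum())
    coarseness = 1.0 / coarse_denom if coarse_denom > 0 else 1e6

    if ngp > 1:
        pij = np.outer(pi, pi)
        dij2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = float((pij * dij2).sum() / (ngp * (ngp - 1)) * (s.sum() / n_valid))
    else:
        contrast = 0.0

    busy_denom = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
    busyness = coarse_denom / busy_denom if busy_denom > 0 else 0.0

    num = np.abs(ii[:, None] - ii[None, :]) * (
        (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
        / (pi[:, None] + pi[None, :])
    )
    complexity = float(num.sum()) / n_valid

    s_total = float(si.sum())
    if s_total > 0:
        strength = float(
            ((pi[:, None] + pi[None, :]) * (ii[:, None] - ii[None, :]) ** 2).sum()
        ) / s_total
    else:
        strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


TEXTURE_COMPUTERS = {
    "glcm": compute_glcm,
    "glrlm": compute_glrlm,
    "glszm": compute_glszm,
    "gldm": compute_gldm,
    "ngtdm": compute_ngtdm,
}


def compute_texture_family(family: str, levels: np.ndarray) -> Dict[str, float]:
    """Dispatch on family name; ``levels`` is the discretized region."""
    if family not in TEXTURE_COMPUTERS:
        raise ValueError(f"unknown texture family {family!r}")
    return TEXTURE_COMPUTERS[family](levels)
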