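"""First-order intensity statistics and intensity discretization."""

from __future__ import annotations

from typing import Dict

import numpy as np

from .registry import FIRSTORDER_FEATURES


def discretize(values: np.ndarray, n_bins: int = 32, bin_width: float | None = None) -> np.ndarray:
    """Map intensities to integer bin labels 1..B.

    Fixed-bin-count mode (default): B equal-width bins spanning the
    region's [min, max]; the maximum maps to bin B and a constant region
    collapses to bin 1.  Fixed-bin-width mode bins relative to the
    region minimum.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    lo, hi = values.min(), values.max()
    if bin_width is not None:
        labels = np.floor((values - lo) / bin_width).astype(np.int64) + 1
        return labels
    if hi <= lo:
        return np.ones(values.shape, dtype=np.int64)
    width = (hi - lo) / n_bins
    labels = np.floor((values - lo) / width).astype(np.int64) + 1
    return np.minimum(labels, n_bins)


def compute_first_order(
    values: np.ndarray,
    voxel_volume: float = 1.0,
    n_bins: int = 32,
    discretized: np.ndarray | None = None,
) -> Dict[str, float]:
    """The 18 first-order features of an intensity sample.

    Entropy and uniformity are computed on the discretized values; every
    moment-based feature of a constant sample is defined as 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("need at least one value")
    if discretized is None:
        discretized = discretize(x, n_bins=n_bins)
    counts = np.bincount(discretized)[1:]
    p = counts[counts > 0] / x.size

    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    centered = x - mean
    if sd > 0:
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    energy = float(np.sum(x**2))

    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(centered).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }


assert tuple(
    compute_first_order(np.array([1.0, 2.0])).keys()
) == FIRSTORDER_FEATURES
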