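"""Independent brute-force oracles used only by the tests.

Every function here recomputes a quantity by direct enumeration, on a
code path deliberately separate from the package's vectorized engine, so
agreement between the two is a meaningful check.
"""

from __future__ import annotations

import numpy as np


def arc_length_point(points: np.ndarray, fraction: float) -> np.ndarray:
    """Point at a given arc-length fraction, by cumulative segment sums."""
    seg = [np.linalg.norm(points[i + 1] - points[i]) for i in range(len(points) - 1)]
    total = sum(seg)
    target = fraction * total
    acc = 0.0
    for i, L in enumerate(seg):
        if acc + L >= target - 1e-12:
            t = (target - acc) / L if L > 0 else 0.0
            return points[i] + t * (points[i + 1] - points[i])
        acc += L
    return points[-1]


def mdf_bruteforce(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Mean pointwise distance minimized over reversal, by direct loops."""
    n = len(a)
    direct = sum(np.linalg.norm(a[i] - b[i]) for i in range(n)) / n
    flipped = sum(np.linalg.norm(a[i] - b[n - 1 - i]) for i in range(n)) / n
    return (flipped, True) if flipped < direct else (direct, False)


def rasterize_fine(points: np.ndarray, shape, affine, step: float) -> set:
    """Voxels visited by a polyline, walked segment-by-segment at ``step``."""
    inv = np.linalg.inv(affine)
    visited = set()
    for i in range(len(points) - 1):
        seg = points[i + 1] - points[i]
        L = np.linalg.norm(seg)
        n = max(int(np.ceil(L / step)), 1)
        for k in range(n + 1):
            p = points[i] + seg * (k / n)
            idx = inv[:3, :3] @ p + inv[:3, 3]
            vox = tuple(int(np.ceil(c - 0.5)) for c in idx)
            if all(0 <= vox[d] < shape[d] for d in range(3)):
                visited.add(vox)
    return visited


def first_order_direct(x: np.ndarray) -> dict:
    """First-order statistics by direct formula, no shared helpers."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    return {
        "Energy": sum(v**2 for v in x),
        "Mean": mean,
        "Variance": var,
        "Minimum": min(x),
        "Maximum": max(x),
        "Range": max(x) - min(x),
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RootMeanSquared": (sum(v**2 for v in x) / n) ** 0.5,
    }


def glcm_pairs_bruteforce(levels: np.ndarray, direction: tuple) -> np.ndarray:
    """Symmetric co-occurrence matrix by enumerating every voxel pair."""
    n = int(levels.max())
    P = np.zeros((n, n))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                i = levels[x, y, z]
                if i == 0:
                    continue
                for sign in (1, -1):
                    nx = x + sign * direction[0]
                    ny = y + sign * direction[1]
                    nz = z + sign * direction[2]
                    if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                        continue
                    j = levels[nx, ny, nz]
                    if j > 0:
                        P[i - 1, j - 1] += 1
    return P


def glcm_contrast_from_matrix(P: np.ndarray) -> float:
    s = P.sum()
    if s == 0:
        return 0.0
    total = 0.0
    n = P.shape[0]
    for i in range(n):
        for j in range(n):
            total += (i - j) ** 2 * P[i, j] / s
    return total


def glcm_features_bruteforce(levels: np.ndarray) -> dict:
    """Direction-averaged GLCM features by pairwise enumeration.

    Covers a representative subset of the family (contrast, joint
    energy/entropy, maximum probability, autocorrelation).
    """
    dirs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
    feats = {"Contrast": [], "JointEnergy": [], "JointEntropy": [],
             "MaximumProbability": [], "Autocorrelation": []}
    for d in dirs:
        P = glcm_pairs_bruteforce(levels, d)
        s = P.sum()
        if s == 0:
            for k in feats:
                feats[k].append(0.0)
            continue
        p = P / s
        feats["Contrast"].append(glcm_contrast_from_matrix(P))
        feats["JointEnergy"].append(float((p**2).sum()))
        feats["JointEntropy"].append(float(-sum(
            v * np.log2(v) for v in p.ravel() if v > 0
        )))
        feats["MaximumProbability"].append(float(p.max()))
        auto = 0.0
        for i in range(P.shape[0]):
            for j in range(P.shape[1]):
                auto += (i + 1) * (j + 1) * p[i, j]
        feats["Autocorrelation"].append(auto)
    return {k: float(np.mean(v)) for k, v in feats.items()}


def runs_bruteforce(levels: np.ndarray, direction: tuple) -> dict:
    """Run-length histogram {(level, length): count} by explicit walking."""
    shape = levels.shape
    d = np.asarray(direction)
    runs: dict = {}
    starts = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                prev = np.asarray([x, y, z]) - d
                if not all(0 <= prev[k] < shape[k] for k in range(3)):
                    starts.append((x, y, z))
    for start in starts:
        pos = np.asarray(start)
        line = []
        while all(0 <= pos[k] < shape[k] for k in range(3)):
            line.append(levels[tuple(pos)])
            pos = pos + d
        i = 0
        while i < len(line):
            if line[i] == 0:
                i += 1
                continue
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            key = (int(line[i]), j - i)
            runs[key] = runs.get(key, 0) + 1
            i = j
    return runs


def dice_bruteforce(a: np.ndarray, b: np.ndarray, k: int) -> float:
    ak = a == k
    bk = b == k
    denom = ak.sum() + bk.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(ak, bk).sum() / denom
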