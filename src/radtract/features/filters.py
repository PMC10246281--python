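"""Image filter bank: Laplacian-of-Gaussian and stationary wavelet bands.

The default bank holds 11 derived images: three LoG responses at sigmas
of 1, 2 and 3 mm and the 8 sub-bands of a single-level separable 3-D
stationary wavelet transform (Coiflet-1), all on the original voxel
grid.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pywt
from scipy import ndimage

from ..core_io import ScalarImage

DEFAULT_LOG_SIGMAS = (1.0, 2.0, 3.0)
DEFAULT_WAVELET = "coif1"


def log_filter(img: ScalarImage, sigma_mm: float) -> ScalarImage:
    """Laplacian-of-Gaussian response at a physical scale in mm."""
    if sigma_mm <= 0:
        raise ValueError("LoG sigma must be positive")
    sigma_vox = sigma_mm / img.voxel_sizes
    # generous kernel truncation: a constant image must map to ~0, which
    # a 4-sigma kernel misses at the 1e-4 level
    out = ndimage.gaussian_laplace(
        img.voxels.astype(float), sigma=sigma_vox, truncate=8.0
    )
    return ScalarImage(out, img.affine)


def wavelet_bands(img: ScalarImage, wavelet: str = DEFAULT_WAVELET) -> Dict[str, ScalarImage]:
    """Single-level undecimated 3-D wavelet decomposition, 8 sub-bands.

    Band names use L (low-pass) and H (high-pass) per axis, LLL..HHH.
    The stationary transform keeps every band on the original grid;
    odd-sized axes are symmetrically padded to even length and cropped
    back.
    """
    data = img.voxels.astype(float)
    pad = [(0, s % 2) for s in data.shape]
    padded = np.pad(data, pad, mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet, level=1, start_level=0)[0]
    out = {}
    for key, band in coeffs.items():
        name = key.upper().replace("A", "L").replace("D", "H")
        crop = band[tuple(slice(0, s) for s in data.shape)]
        out[f"wavelet-{name}"] = ScalarImage(crop, img.affine)
    return out


def apply_filter_bank(
    img: ScalarImage,
    log_sigmas: Sequence[float] = DEFAULT_LOG_SIGMAS,
    wavelet: str = DEFAULT_WAVELET,
) -> Dict[str, ScalarImage]:
    """All derived images, keyed by filter name; 'original' comes first."""
    bank: Dict[str, ScalarImage] = {"original": img}
    for s in log_sigmas:
        bank[f"log-sigma-{s:g}mm"] = log_filter(img, s)
    bank.update(wavelet_bands(img, wavelet))
    return bank
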