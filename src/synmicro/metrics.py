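"""Image-quality metrics for comparing real and synthetic volumes.

NRMSE, SSIM, ZNCC and PSNR — the standard pixel-level agreement scores for
paired volumes — plus the 1D intensity profile used for qualitative
depth-decay comparisons. NRMSE and PSNR are normalized by the intensity
range of the first (reference) argument; SSIM uses 7^3 windows with the
standard constants via scikit-image.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .volumes import as_array

__all__ = ["nrmse", "ssim", "zncc", "psnr", "intensity_profile"]


def _pair(a, b):
    a = np.asarray(as_array(a), dtype=np.float64)
    b = np.asarray(as_array(b), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"volumes must be aligned: {a.shape} vs {b.shape}")
    return a, b


def nrmse(a, b) -> float:
    """Root mean square error normalized by the reference (first arg) range."""
    a, b = _pair(a, b)
    rng = float(a.max() - a.min())
    if rng == 0:
        raise ValueError("reference volume has zero intensity range")
    return float(np.sqrt(np.mean((a - b) ** 2)) / rng)


def ssim(a, b, win_size: int = 7) -> float:
    """Mean structural similarity over 3D local windows (standard constants)."""
    a, b = _pair(a, b)
    rng = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    return float(structural_similarity(a, b, win_size=win_size,
                                       data_range=rng if rng > 0 else 1.0))


def zncc(a, b) -> float:
    """Zero-mean normalized cross-correlation (Pearson r of flattened voxels)."""
    a, b = _pair(a, b)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(np.sum(a * a)), np.sqrt(np.sum(b * b))
    if na == 0 or nb == 0:
        raise ValueError("ZNCC undefined for a zero-variance volume")
    return float(np.sum(a * b) / (na * nb))


def psnr(a, b) -> float:
    """Peak signal-to-noise ratio in dB, peak = reference range; +inf if equal."""
    a, b = _pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return float("inf")
    peak = float(a.max() - a.min())
    if peak == 0:
        raise ValueError("reference volume has zero intensity range")
    return float(10.0 * np.log10(peak ** 2 / mse))


def intensity_profile(volume, plane: str = "xz") -> np.ndarray:
    """1D intensity profile of a center slice, integrated over one axis.

    ``plane`` selects the slice (volumes are (z, y, x)): ``"xz"`` takes the
    center-y slice and sums over z, giving a profile along x; ``"yz"`` the
    center-x slice summed over z (profile along y); ``"xy"`` the center-z
    slice summed over y (profile along x).
    """
    arr = np.asarray(as_array(volume), dtype=np.float64)
    nz, ny, nx = arr.shape
    if plane == "xz":
        return arr[:, ny // 2, :].sum(axis=0)
    if plane == "yz":
        return arr[:, :, nx // 2].sum(axis=0)
    if plane == "xy":
        return arr[nz // 2, :, :].sum(axis=0)
    raise ValueError("plane must be one of 'xz', 'yz', 'xy'")
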