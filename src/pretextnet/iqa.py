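"""Full-reference image-quality metrics: MSE, MAE, PSNR, SSIM, HaarPSI.

All functions accept 2-D arrays (or :class:`~pretextnet.core_io.GrayImage`)
on the canonical [0, 1] scale unless stated otherwise. PSNR is reported on
the 0-255 scale (``max_val=255``) to match conventional dB magnitudes for
8-bit images; the conversion from the canonical scale is internal.

SSIM uses an 11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03, L=1 on
the canonical scale, with 'valid' window placement (borders cropped).
``ssim_with_gradient`` exposes the analytic gradient of the mean SSIM with
respect to the first argument; the restoration loss reuses it so the loss
and the reported metric share one implementation.

HaarPSI follows the full formulation of its original reference (grayscale
path): coefficients from three Haar-wavelet scales, local similarities from
the two high-frequency scales, importance weights from the third scale,
logistic mapping with steepness alpha=4.2 and stability constant C=30 on
the 0-255 coefficient scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from pretextnet.core_io import GrayImage

__all__ = [
    "QualityReport",
    "mse",
    "mae",
    "psnr",
    "ssim",
    "ssim_with_gradient",
    "haarpsi",
    "haar_coefficients",
    "compute_quality",
]

SSIM_WIN_SIZE = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03
HAARPSI_C = 30.0
HAARPSI_ALPHA = 4.2


def _as_array(img) -> np.ndarray:
    if isinstance(img, GrayImage):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(gt, pred) -> float:
    gt, pred = _as_array(gt), _as_array(pred)
    _check_shapes(gt, pred)
    return float(np.mean((gt - pred) ** 2))


def mae(gt, pred) -> float:
    gt, pred = _as_array(gt), _as_array(pred)
    _check_shapes(gt, pred)
    return float(np.mean(np.abs(gt - pred)))


def psnr(gt, pred, max_val: float = 255.0) -> float:
    """``10 * log10(max_val**2 / MSE)`` with MSE on the ``max_val`` scale.

    Inputs are canonical [0, 1] images; they are scaled by ``max_val``
    internally. Returns ``inf`` when the images are identical.
    """
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    gt, pred = _as_array(gt), _as_array(pred)
    _check_shapes(gt, pred)
    err = mse(gt * max_val, pred * max_val)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val**2 / err))


# ---------------------------------------------------------------------------
# SSIM


def _ssim_window(win_size: int, sigma: float | None) -> np.ndarray:
    if sigma is None:
        w = np.ones((win_size, win_size))
    else:
        half = (win_size - 1) / 2
        ax = np.arange(win_size) - half
        g = np.exp(-(ax**2) / (2 * sigma**2))
        w = np.outer(g, g)
    return w / w.sum()


def _ssim_terms(x, y, window, K1, K2, L):
    C1 = (K1 * L) ** 2
    C2 = (K2 * L) ** 2
    # symmetric window: correlation == convolution
    w = lambda a: convolve2d(a, window, mode="valid")
    ux, uy = w(x), w(y)
    vx = w(x * x) - ux * ux
    vy = w(y * y) - uy * uy
    vxy = w(x * y) - ux * uy
    A1 = 2 * ux * uy + C1
    A2 = 2 * vxy + C2
    B1 = ux * ux + uy * uy + C1
    B2 = vx + vy + C2
    S = (A1 * A2) / (B1 * B2)
    return S, (ux, uy, vx, vy, vxy, A1, A2, B1, B2)


def ssim(
    x,
    y,
    win_size: int = SSIM_WIN_SIZE,
    sigma: float | None = SSIM_SIGMA,
    K1: float = SSIM_K1,
    K2: float = SSIM_K2,
    L: float = 1.0,
) -> float:
    """Mean local SSIM over valid sliding windows.

    ``sigma=None`` selects a uniform window, in which case a window the size
    of the whole image reduces to the single-window scalar formula with
    population (biased) variance and covariance.
    """
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    if L <= 0:
        raise ValueError("L must be positive")
    if win_size > min(x.shape):
        raise ValueError(
            f"window size {win_size} exceeds image dimension {min(x.shape)}"
        )
    window = _ssim_window(win_size, sigma)
    S, _ = _ssim_terms(x, y, window, K1, K2, L)
    return float(S.mean())


def ssim_with_gradient(
    x,
    y,
    win_size: int = SSIM_WIN_SIZE,
    sigma: float | None = SSIM_SIGMA,
    K1: float = SSIM_K1,
    K2: float = SSIM_K2,
    L: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Mean SSIM and its analytic gradient with respect to ``x``."""
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    if win_size > min(x.shape):
        raise ValueError("window larger than image")
    window = _ssim_window(win_size, sigma)
    S, (ux, uy, vx, vy, vxy, A1, A2, B1, B2) = _ssim_terms(x, y, window, K1, K2, L)
    M = S.size
    denom = B1 * B2
    # partials of the local statistic; P = w*x, Q = w*(x^2), R = w*(x*y)
    dS_du = 2 * uy * A2 / denom - 2 * ux * S / B1
    dS_dvx = -S / B2
    dS_dvxy = 2 * A1 / denom
    dS_dP = dS_du - 2 * ux * dS_dvx - uy * dS_dvxy
    back = lambda g: convolve2d(g, window, mode="full")
    grad = (back(dS_dP) + back(dS_dvx) * 2 * x + back(dS_dvxy) * y) / M
    return float(S.mean()), grad


# ---------------------------------------------------------------------------
# HaarPSI


def _haar_filter(scale: int) -> np.ndarray:
    size = 2**scale
    f = np.full((size, size), 2.0**-scale)
    f[: size // 2, :] *= -1.0
    return f


def haar_coefficients(arr: np.ndarray, scale: int, orientation: int) -> np.ndarray:
    """Haar wavelet coefficients at ``scale`` (1-based).

    Orientation 0 responds to horizontal edges (vertical intensity change),
    orientation 1 to vertical edges. Same-size output, symmetric borders.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if orientation not in (0, 1):
        raise ValueError("orientation must be 0 or 1")
    f = _haar_filter(scale)
    if orientation == 1:
        f = f.T
    return convolve2d(np.asarray(arr, dtype=np.float64), f, mode="same", boundary="symm")


def _subsample2(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape
    h2, w2 = h - h % 2, w - w % 2
    a = arr[:h2, :w2]
    return 0.25 * (a[0::2, 0::2] + a[0::2, 1::2] + a[1::2, 0::2] + a[1::2, 1::2])


def _logistic(x, alpha):
    return 1.0 / (1.0 + np.exp(-alpha * x))


def haarpsi(gt, pred) -> float:
    """Haar-wavelet perceptual similarity index in [0, 1] (grayscale)."""
    gt, pred = _as_array(gt), _as_array(pred)
    _check_shapes(gt, pred)
    if min(gt.shape) < 8:
        raise ValueError("images must be at least 8 pixels in each dimension")
    a = _subsample2(gt * 255.0)
    b = _subsample2(pred * 255.0)

    C, alpha = HAARPSI_C, HAARPSI_ALPHA
    sim_num = 0.0
    sim_den = 0.0
    for orientation in (0, 1):
        mags_a = [np.abs(haar_coefficients(a, j, orientation)) for j in (1, 2, 3)]
        mags_b = [np.abs(haar_coefficients(b, j, orientation)) for j in (1, 2, 3)]
        local = np.zeros_like(a)
        for j in (0, 1):  # the two high-frequency scales
            ca, cb = mags_a[j], mags_b[j]
            local += (2 * ca * cb + C) / (ca**2 + cb**2 + C)
        local /= 2.0
        weight = np.maximum(mags_a[2], mags_b[2])
        sim_num += float(np.sum(_logistic(local, alpha) * weight))
        sim_den += float(np.sum(weight))
    if sim_den == 0.0:
        return 1.0
    mean_sim = sim_num / sim_den
    return float((np.log(mean_sim / (1.0 - mean_sim)) / alpha) ** 2)


# ---------------------------------------------------------------------------
# reporting


@dataclass
class QualityReport:
    psnr: float
    ssim: float
    haarpsi: float
    mse: float
    mae: float


def compute_quality(gt, pred) -> QualityReport:
    """All five metrics for one image pair on the canonical scale."""
    return QualityReport(
        psnr=psnr(gt, pred),
        ssim=ssim(gt, pred),
        haarpsi=haarpsi(gt, pred),
        mse=mse(gt, pred),
        mae=mae(gt, pred),
    )
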