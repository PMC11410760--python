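"""Stochastic Gaussian-noise and Gaussian-blur degradation of images.

Noise: zero-mean unit-variance Gaussian scaled by a variance factor drawn
uniformly from a predefined list (defaults ``[0.02, 0.04, 0.06, 0.08, 0.1]``),
added per pixel and clipped back to [0, 1].

Blur: normalized 2-D Gaussian kernel of odd size k drawn from
``[3, 5, 7, 9]`` with the auto-sigma convention
``sigma = 0.3 * ((k - 1) / 2 - 1) + 0.8`` and reflective border handling.

Parameter draws use a dedicated random stream per image index so that
changing dataset order does not reshuffle all draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from pretextnet.core_io import GrayImage

__all__ = [
    "NoiseSpec",
    "BlurSpec",
    "PairedSample",
    "DEFAULT_VARIANCE_FACTORS",
    "DEFAULT_KERNEL_SIZES",
    "add_gaussian_noise",
    "add_gaussian_blur",
    "gaussian_kernel",
    "auto_sigma",
    "degrade_dataset",
]

DEFAULT_VARIANCE_FACTORS = (0.02, 0.04, 0.06, 0.08, 0.1)
DEFAULT_KERNEL_SIZES = (3, 5, 7, 9)


@dataclass
class NoiseSpec:
    variance_factors: tuple[float, ...] = DEFAULT_VARIANCE_FACTORS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.variance_factors) == 0:
            raise ValueError("variance_factors must be non-empty")
        if any(f <= 0 for f in self.variance_factors):
            raise ValueError("variance factors must be positive")


@dataclass
class BlurSpec:
    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.kernel_sizes) == 0:
            raise ValueError("kernel_sizes must be non-empty")
        if any(k < 3 or k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd and >= 3")


@dataclass
class PairedSample:
    """A (degraded, clean) restoration training pair."""

    degraded: GrayImage
    clean: GrayImage
    applied_parameter: float
    image_id: str = ""
    mode: str = ""

    def __post_init__(self) -> None:
        if self.degraded.shape != self.clean.shape:
            raise ValueError("degraded and clean shapes differ")


def add_gaussian_noise(img: GrayImage, variance_factor: float, seed: int = 0) -> GrayImage:
    """``clip(img + factor * N(0, 1), 0, 1)`` with i.i.d. per-pixel noise."""
    if variance_factor <= 0:
        raise ValueError("variance_factor must be positive")
    rng = np.random.default_rng(seed)
    noisy = img.pixels + variance_factor * rng.standard_normal(img.shape)
    return GrayImage(np.clip(noisy, 0.0, 1.0), img.source_depth)


def auto_sigma(kernel_size: int) -> float:
    """Sigma automatically derived from the kernel size."""
    return 0.3 * ((kernel_size - 1) / 2 - 1) + 0.8


def gaussian_kernel(kernel_size: int) -> np.ndarray:
    """Normalized 2-D Gaussian kernel (sums to 1) with the auto sigma."""
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 3")
    sigma = auto_sigma(kernel_size)
    half = kernel_size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2 * sigma**2))
    kernel = np.outer(g1, g1)
    return kernel / kernel.sum()


def add_gaussian_blur(img: GrayImage, kernel_size: int) -> GrayImage:
    """Convolve with the normalized Gaussian kernel, reflective borders."""
    kernel = gaussian_kernel(kernel_size)
    blurred = ndimage.convolve(img.pixels, kernel, mode="reflect")
    return GrayImage(np.clip(blurred, 0.0, 1.0), img.source_depth)


def degrade_dataset(
    images: Sequence[tuple[str, GrayImage]] | dict[str, GrayImage],
    mode: str,
    spec: NoiseSpec | BlurSpec,
) -> list[PairedSample]:
    """Degrade each image with a parameter drawn from the spec's list.

    ``images`` is a sequence of ``(image_id, GrayImage)`` (or a mapping,
    iterated in sorted-id order). The draw for image index ``i`` comes from
    the stream seeded with ``(spec.seed, i)``.
    """
    if isinstance(images, dict):
        items = sorted(images.items())
    else:
        items = list(images)
    if not items:
        raise ValueError("image list is empty")
    if mode not in ("noise", "blur"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "noise" and not isinstance(spec, NoiseSpec):
        raise ValueError("noise mode needs a NoiseSpec")
    if mode == "blur" and not isinstance(spec, BlurSpec):
        raise ValueError("blur mode needs a BlurSpec")

    params = (
        spec.variance_factors if isinstance(spec, NoiseSpec) else spec.kernel_sizes
    )
    samples: list[PairedSample] = []
    for i, (image_id, img) in enumerate(items):
        rng = np.random.default_rng([spec.seed, i])
        param = params[int(rng.integers(0, len(params)))]
        if mode == "noise":
            noise_seed = int(rng.integers(0, 2**31 - 1))
            degraded = add_gaussian_noise(img, float(param), seed=noise_seed)
        else:
            degraded = add_gaussian_blur(img, int(param))
        samples.append(
            PairedSample(
                degraded=degraded,
                clean=GrayImage(img.pixels.copy(), img.source_depth),
                applied_parameter=float(param),
                image_id=image_id,
                mode=mode,
            )
        )
    return samples
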