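"""Score-CAM activation maps and extreme-point bounding boxes.

Score-CAM is gradient-free: each channel of the deepest convolutional layer
is upsampled to the input size, min-max normalized, used to mask the input,
and the masked input's forward-pass softmax score on the target class
becomes that channel's weight. The map is the min-max-normalized ReLU of
the weighted sum. Maps are binarized at a fraction of their maximum and the
surviving pixels' extreme coordinates give a single inclusive bounding box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from pretextnet.core_io import GrayImage, resize
from pretextnet.transfer import Classifier

__all__ = [
    "ActivationMap",
    "BoundingBox",
    "score_cam",
    "map_to_bbox",
    "box_iou",
    "EmptyBoxError",
]

DEFAULT_REL_THRESHOLD = 0.2


class EmptyBoxError(ValueError):
    """No pixel survived the binarization threshold."""


@dataclass
class ActivationMap:
    values: np.ndarray  # (H, W) in [0, 1], input-sized
    target_class: int
    source_layer: str = "encoder.b4.conv2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("activation map must be 2-D")
        if self.values.min() < -1e-9 or self.values.max() > 1.0 + 1e-9:
            raise ValueError("activation map must lie in [0, 1]")


@dataclass(frozen=True)
class BoundingBox:
    """0-based, inclusive pixel box."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError("degenerate bounding box")
        if min(self.row_min, self.col_min) < 0:
            raise ValueError("negative box coordinates")

    @property
    def area(self) -> int:
        return (self.row_max - self.row_min + 1) * (self.col_max - self.col_min + 1)


def _upsample_channel(channel: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    lo, hi = float(channel.min()), float(channel.max())
    span = hi - lo
    scaled = np.zeros_like(channel) if span == 0 else (channel - lo) / span
    return resize(GrayImage(np.clip(scaled, 0, 1)), size).pixels


def score_cam(
    classifier: Classifier,
    image: GrayImage | np.ndarray,
    target_class: int,
    batch_size: int = 16,
) -> ActivationMap:
    """Class activation map from the deepest convolutional layer."""
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 or 1")
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    size = pixels.shape

    acts = classifier.feature_maps(pixels[None].astype(np.float32))[0]  # (C, h, w)
    n_channels = acts.shape[0]
    upsampled = np.stack(
        [_upsample_channel(acts[k].astype(np.float64), size) for k in range(n_channels)]
    )

    if np.all(upsampled == 0):
        warnings.warn("all activation channels are constant; returning a zero map")
        return ActivationMap(np.zeros(size), target_class)

    weights = np.empty(n_channels)
    for start in range(0, n_channels, batch_size):
        masked = upsampled[start : start + batch_size] * pixels[None]
        probs = classifier.predict_proba(masked.astype(np.float32))
        weights[start : start + batch_size] = probs[:, target_class]

    combined = np.tensordot(weights, upsampled, axes=(0, 0))
    combined = np.maximum(combined, 0.0)
    span = combined.max() - combined.min()
    if span == 0:
        warnings.warn("combined activation map is constant; returning a zero map")
        return ActivationMap(np.zeros(size), target_class)
    return ActivationMap((combined - combined.min()) / span, target_class)


def map_to_bbox(
    amap: ActivationMap, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> BoundingBox:
    """Extreme-point box of pixels above ``rel_threshold * max(map)``."""
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    values = amap.values
    cutoff = rel_threshold * values.max()
    rows, cols = np.nonzero(values > cutoff) if values.max() > 0 else ((), ())
    if len(rows) == 0:
        raise EmptyBoxError("no pixel survived the threshold")
    return BoundingBox(
        int(np.min(rows)), int(np.min(cols)), int(np.max(rows)), int(np.max(cols))
    )


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union with inclusive pixel counting."""
    inter_rows = min(a.row_max, b.row_max) - max(a.row_min, b.row_min) + 1
    inter_cols = min(a.col_max, b.col_max) - max(a.col_min, b.col_min) + 1
    inter = max(inter_rows, 0) * max(inter_cols, 0)
    union = a.area + b.area - inter
    return inter / union
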