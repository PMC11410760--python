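"""Image and table I/O, canonical intensity representation, and run plumbing.

Conventions used throughout the package (stated once here, reused elsewhere):

* the canonical internal intensity scale is ``[0, 1]`` floats; the 0-255
  integer scale appears only at file boundaries;
* arrays are row-major and 0-based; bounding boxes are inclusive on both
  ends;
* RGB inputs are collapsed to grayscale by the unweighted channel mean;
* quantization at save time rounds half away from zero.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "GrayImage",
    "LabeledRecord",
    "RunConfig",
    "load_image",
    "save_image",
    "resize",
    "crop_to_mask_bbox",
    "read_label_table",
    "write_label_table",
    "derive_seed",
    "get_logger",
]

logger = logging.getLogger("pretextnet")


@dataclass
class GrayImage:
    """A single-channel image on the canonical ``[0, 1]`` scale."""

    pixels: np.ndarray
    source_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {self.pixels.shape}")
        if self.pixels.size == 0:
            raise ValueError("zero-size image")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("image values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabeledRecord:
    """One labeled image: 0 = normal, 1 = abnormal."""

    image_id: str
    patient_id: str
    label: int
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.split not in ("train", "val", "test", "unassigned"):
            raise ValueError(f"unknown split {self.split!r}")


def load_image(path: str | Path) -> GrayImage:
    """Load a PNG/JPEG as a :class:`GrayImage`.

    Multi-channel inputs are collapsed by the unweighted channel mean;
    values are scaled to [0, 1] by dividing by ``2**depth - 1``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # pragma: no cover - PIL error classes vary
        raise IOError(f"could not decode image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    depth = 16 if arr.dtype == np.uint16 else 8
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return GrayImage(arr / (2**depth - 1), source_depth=depth)


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/JPEG, rounding half away from zero."""
    path = Path(path)
    q = np.floor(img.pixels * 255.0 + 0.5).astype(np.uint8)
    try:
        Image.fromarray(q, mode="L").save(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"could not write image {path}: {exc}") from exc


def resize(img: GrayImage, size: tuple[int, int]) -> GrayImage:
    """Bilinear resize to ``size = (height, width)``.

    Pixel centers follow the half-pixel convention: output center ``i`` maps
    to input coordinate ``(i + 0.5) * h_in / h_out - 0.5``, clamped at the
    edges.
    """
    h_out, w_out = int(size[0]), int(size[1])
    if h_out <= 0 or w_out <= 0:
        raise ValueError(f"target size must be positive, got {size}")
    if (h_out, w_out) == img.shape:
        return GrayImage(img.pixels.copy(), source_depth=img.source_depth)
    out = _bilinear(img.pixels, h_out, w_out)
    return GrayImage(np.clip(out, 0.0, 1.0), source_depth=img.source_depth)


def _bilinear(arr: np.ndarray, h_out: int, w_out: int) -> np.ndarray:
    h_in, w_in = arr.shape
    rows = (np.arange(h_out) + 0.5) * h_in / h_out - 0.5
    cols = (np.arange(w_out) + 0.5) * w_in / w_out - 0.5
    rows = np.clip(rows, 0, h_in - 1)
    cols = np.clip(cols, 0, w_in - 1)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    r1 = np.minimum(r0 + 1, h_in - 1)
    c1 = np.minimum(c0 + 1, w_in - 1)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    top = arr[np.ix_(r0, c0)] * (1 - fc) + arr[np.ix_(r0, c1)] * fc
    bot = arr[np.ix_(r1, c0)] * (1 - fc) + arr[np.ix_(r1, c1)] * fc
    return top * (1 - fr[:, 0])[:, None] + bot * fr[:, 0][:, None]


def crop_to_mask_bbox(img: GrayImage, mask: np.ndarray) -> GrayImage:
    """Crop to the tight inclusive bounding box of the true mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("mask has no true pixels")
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    return GrayImage(img.pixels[r0 : r1 + 1, c0 : c1 + 1].copy(), img.source_depth)


# ---------------------------------------------------------------------------
# label tables


def read_label_table(path: str | Path) -> list[LabeledRecord]:
    df = pd.read_csv(path, dtype={"image_id": str, "patient_id": str})
    required = {"image_id", "patient_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        split = getattr(row, "split", "unassigned")
        records.append(
            LabeledRecord(row.image_id, row.patient_id, int(row.label), split)
        )
    return records


def write_label_table(records: list[LabeledRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.image_id, r.patient_id, r.label, r.split) for r in records],
        columns=["image_id", "patient_id", "label", "split"],
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Global run configuration; every stage seed derives from ``seed``."""

    seed: int = 0
    image_size: tuple[int, int] = (224, 224)
    paths: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        size = raw.get("image_size", (224, 224))
        return cls(
            seed=int(raw.get("seed", 0)),
            image_size=(int(size[0]), int(size[1])),
            paths=dict(raw.get("paths", {})),
            stages={k: dict(v) for k, v in raw.get("stages", {}).items()},
        )

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def stage_params(self, stage: str) -> dict[str, Any]:
        return dict(self.stages.get(stage, {}))


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of the global seed and the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def get_logger(log_file: str | Path | None = None) -> logging.Logger:
    """Package logger with structured 'timestamp stage level message' lines."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(fh)
    return logger
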