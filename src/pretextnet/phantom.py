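"""Synthetic chest-like grayscale phantoms and labeled cohorts.

The phantoms are deliberately minimal: two filled lung-field ellipses
brighter than the background, rib-like horizontal banding, and (for abnormal
phantoms) Gaussian-profile focal opacities placed inside a lung field. They
emulate the contrast structure that the restorer and the classifier must
exploit, not radiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pretextnet.core_io import GrayImage, LabeledRecord, save_image, write_label_table

__all__ = [
    "PhantomSpec",
    "Cohort",
    "generate_phantom",
    "generate_cohort",
    "patient_split",
    "write_cohort",
]

DEFAULT_FRACTIONS = (0.70, 0.10, 0.20)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom."""

    size: tuple[int, int] = (64, 64)
    abnormal: bool = False
    opacity_count: int = 0
    opacity_radius_range: tuple[int, int] = (4, 8)
    opacity_amplitude: float = 0.30
    # diffuse same-mass patches added to normal phantoms so that global
    # brightness alone does not separate the classes; the discriminative cue
    # is compact (opacity) vs diffuse (distractor) structure
    distractor_count: int = 0
    background_level: float = 0.12
    lung_level: float = 0.55
    rib_count: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h <= 0 or w <= 0:
            raise ValueError(f"invalid phantom size {self.size}")
        if self.opacity_count < 0:
            raise ValueError("opacity_count must be >= 0")
        if not self.abnormal and self.opacity_count != 0:
            raise ValueError("normal phantoms must have opacity_count == 0")
        if self.abnormal and self.opacity_count == 0:
            raise ValueError("abnormal phantoms need opacity_count >= 1")
        lo, hi = self.opacity_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid opacity_radius_range")
        if hi >= min(h, w) / 2:
            raise ValueError("opacity radius too large for phantom size")
        for level in (self.background_level, self.lung_level):
            if not 0.0 <= level <= 1.0:
                raise ValueError("intensity levels must lie in [0, 1]")


@dataclass
class Cohort:
    """A labeled phantom collection with per-image ground-truth boxes."""

    records: list[LabeledRecord]
    images: dict[str, GrayImage]
    truth_boxes: dict[str, list[tuple[int, int, int, int]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.image_id not in self.images:
                raise ValueError(f"record {rec.image_id} has no image")
            if rec.label == 1 and not self.truth_boxes.get(rec.image_id):
                raise ValueError(f"abnormal record {rec.image_id} has no truth box")

    def subset(self, split: str) -> "Cohort":
        recs = [r for r in self.records if r.split == split]
        ids = {r.image_id for r in recs}
        return Cohort(
            records=recs,
            images={k: v for k, v in self.images.items() if k in ids},
            truth_boxes={k: v for k, v in self.truth_boxes.items() if k in ids},
        )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[GrayImage, list[tuple[int, int, int, int]]]:
    """Render one phantom; pure function of its spec.

    Returns the image and a list of inclusive opacity bounding boxes
    ``(row_min, col_min, row_max, col_max)``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)

    img = np.full((h, w), spec.background_level)

    # two lung-field ellipses with seed-jittered geometry
    lung_masks = []
    for side in (-1.0, 1.0):
        cy = h * (0.52 + 0.04 * (rng.random() - 0.5))
        cx = w * (0.5 + side * (0.22 + 0.02 * (rng.random() - 0.5)))
        ry = h * (0.30 + 0.03 * (rng.random() - 0.5))
        rx = w * (0.14 + 0.02 * (rng.random() - 0.5))
        mask = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
        lung_masks.append(mask)
        level = spec.lung_level + 0.04 * (rng.random() - 0.5)
        img[mask] = level

    # rib-like horizontal banding across the lung fields
    phase = rng.random() * 2 * np.pi
    bands = 0.06 * np.sin(2 * np.pi * spec.rib_count * rr / h + phase)
    any_lung = lung_masks[0] | lung_masks[1]
    img[any_lung] += bands[any_lung]

    boxes: list[tuple[int, int, int, int]] = []
    for _ in range(spec.opacity_count):
        radius = int(rng.integers(spec.opacity_radius_range[0], spec.opacity_radius_range[1] + 1))
        lung = lung_masks[int(rng.integers(0, 2))]
        rows, cols = np.nonzero(lung)
        k = int(rng.integers(0, rows.size))
        cy, cx = int(rows[k]), int(cols[k])
        sigma = radius / 2.0
        blob = spec.opacity_amplitude * np.exp(
            -(((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sigma**2))
        )
        img += blob
        boxes.append(
            (
                max(cy - radius, 0),
                max(cx - radius, 0),
                min(cy + radius, h - 1),
                min(cx + radius, w - 1),
            )
        )

    for _ in range(spec.distractor_count):
        radius = int(rng.integers(spec.opacity_radius_range[0], spec.opacity_radius_range[1] + 1))
        lung = lung_masks[int(rng.integers(0, 2))]
        rows, cols = np.nonzero(lung)
        k = int(rng.integers(0, rows.size))
        cy, cx = int(rows[k]), int(cols[k])
        sigma = 3.0 * radius / 2.0  # 3x wider, 9x weaker: same added mass
        patch = (spec.opacity_amplitude / 9.0) * np.exp(
            -(((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sigma**2))
        )
        img += patch

    img += 0.015 * rng.standard_normal((h, w))
    return GrayImage(np.clip(img, 0.0, 1.0)), boxes


def generate_cohort(
    n: int,
    prevalence: float,
    images_per_patient: tuple[int, int] = (1, 3),
    seed: int = 0,
    size: tuple[int, int] = (64, 64),
) -> Cohort:
    """Generate ``n`` phantoms with ``floor(n * prevalence)`` abnormal images.

    Images are grouped under patients (all images of a patient share one
    label) with per-patient image counts drawn uniformly from
    ``images_per_patient``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    lo, hi = images_per_patient
    if not (1 <= lo <= hi):
        raise ValueError("invalid images_per_patient range")

    rng = np.random.default_rng(seed)
    n_abnormal = int(np.floor(n * prevalence))
    labels = np.array([1] * n_abnormal + [0] * (n - n_abnormal))
    rng.shuffle(labels)

    records: list[LabeledRecord] = []
    images: dict[str, GrayImage] = {}
    truth: dict[str, list[tuple[int, int, int, int]]] = {}

    idx = 0
    patient_no = 0
    while idx < n:
        group = int(rng.integers(lo, hi + 1))
        group = min(group, n - idx)
        # a patient's images share a label; take the label of the first slot
        patient_label = int(labels[idx])
        patient_id = f"pt{patient_no:04d}"
        for _ in range(group):
            if idx >= n:
                break
            if int(labels[idx]) != patient_label:
                # keep label grouping: find a later slot with matching label
                swap = np.nonzero(labels[idx:] == patient_label)[0]
                if swap.size == 0:
                    break
                j = idx + int(swap[0])
                labels[idx], labels[j] = labels[j], labels[idx]
            image_id = f"img{idx:05d}"
            n_structures = int(rng.integers(2, 4))
            spec = PhantomSpec(
                size=size,
                abnormal=bool(patient_label),
                opacity_count=n_structures if patient_label else 0,
                distractor_count=0 if patient_label else n_structures,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            img, boxes = generate_phantom(spec)
            records.append(LabeledRecord(image_id, patient_id, patient_label))
            images[image_id] = img
            if boxes:
                truth[image_id] = boxes
            idx += 1
        patient_no += 1

    return Cohort(records=records, images=images, truth_boxes=truth)


def patient_split(
    cohort: Cohort,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> Cohort:
    """Assign train/val/test splits at the patient level.

    Patients are shuffled with the stage seed, then each patient is greedily
    assigned to the split whose image-count deficit (relative to its target
    fraction) is largest. No patient ever spans two splits.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    patients: dict[str, list[LabeledRecord]] = {}
    for rec in cohort.records:
        patients.setdefault(rec.patient_id, []).append(rec)
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to split")

    rng = np.random.default_rng(seed)
    order = sorted(patients)
    rng.shuffle(order)

    total = len(cohort.records)
    targets = [f * total for f in fractions]
    counts = [0.0, 0.0, 0.0]
    names = ("train", "val", "test")
    assignment: dict[str, str] = {}
    for pid in order:
        deficits = [targets[i] - counts[i] for i in range(3)]
        k = int(np.argmax(deficits))
        assignment[pid] = names[k]
        counts[k] += len(patients[pid])

    new_records = [
        LabeledRecord(r.image_id, r.patient_id, r.label, assignment[r.patient_id])
        for r in cohort.records
    ]
    return Cohort(new_records, dict(cohort.images), dict(cohort.truth_boxes))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write PNGs, the label table, and the truth-box table."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.records:
        save_image(cohort.images[rec.image_id], img_dir / f"{rec.image_id}.png")
    write_label_table(cohort.records, out_dir / "labels.csv")
    rows = [
        (image_id, r0, c0, r1, c1)
        for image_id, boxes in sorted(cohort.truth_boxes.items())
        for (r0, c0, r1, c1) in boxes
    ]
    pd.DataFrame(
        rows, columns=["image_id", "row_min", "col_min", "row_max", "col_max"]
    ).to_csv(out_dir / "truth_boxes.csv", index=False)
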