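"""Encoder transfer: restorer encoder -> binary normal/abnormal classifier.

The trained restorer's encoder is truncated at its deepest convolutional
layer and extended with global average pooling and a dense two-node softmax
head. Fine-tuning uses SGD from a 1e-3 learning rate with the same
plateau/checkpoint regimen as the pretext stage; all encoder layers remain
trainable. The baseline variant differs only in its initialization source.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pretextnet._nnops import (
    SGD,
    Dense,
    GlobalAvgPool,
    Param,
    softmax,
    softmax_cross_entropy,
)
from pretextnet.phantom import Cohort
from pretextnet.pretext import PlateauScheduler, PretextTrainConfig, TrainHistory
from pretextnet.sharp_unet import Restorer, VGGEncoder, load_checkpoint, save_checkpoint

__all__ = [
    "ClassifierTrainConfig",
    "Classifier",
    "truncate_encoder",
    "build_classifier",
    "fine_tune",
    "predict_cohort",
    "write_predictions",
]

INIT_SOURCES = ("denoise_pretext", "deblur_pretext", "external_pretrained", "random")


@dataclass
class ClassifierTrainConfig(PretextTrainConfig):
    threshold: float = 0.5
    # Relative learning rate of the encoder vs the head. 1.0 reproduces the
    # single-rate SGD regimen; desk-scale runs may slow the encoder to keep
    # pretext features from collapsing during the short fine-tune budget.
    encoder_lr_scale: float = 1.0


def truncate_encoder(restorer: Restorer) -> VGGEncoder:
    """Copy the restorer's encoder through its deepest convolution; drop the decoder."""
    if not isinstance(restorer, Restorer):
        raise ValueError("expected a Restorer")
    encoder = VGGEncoder(
        in_channels=1,
        width_multiplier=restorer.width_multiplier,
        rng=np.random.default_rng(0),
    )
    src = restorer.encoder.named_params()
    for name, param in encoder.named_params().items():
        if param.value.shape != src[name].value.shape:
            raise ValueError(f"architecture mismatch at {name}")
        param.value = src[name].value.copy()
    return encoder


class Classifier:
    """VGG encoder + GAP + dense 2-node softmax head."""

    def __init__(
        self,
        encoder: VGGEncoder,
        init_source: str = "random",
        seed: int = 0,
    ):
        if init_source not in INIT_SOURCES:
            raise ValueError(f"unknown init_source {init_source!r}")
        self.encoder = encoder
        self.init_source = init_source
        self.gap = GlobalAvgPool()
        self.head = Dense(encoder.filters[4], 2, np.random.default_rng(seed))
        self._features: np.ndarray | None = None

    @property
    def feature_dim(self) -> int:
        return self.encoder.filters[4]

    def named_params(self) -> dict[str, Param]:
        out = self.encoder.named_params("enc")
        out["head.W"] = self.head.W
        out["head.b"] = self.head.b
        return out

    def params(self) -> list[Param]:
        return list(self.named_params().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.named_params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.named_params().items():
            if k not in state:
                raise ValueError(f"checkpoint missing {k}")
            p.value = np.asarray(state[k], dtype=np.float32).copy()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits (N, 2) for a batch of images (N,H,W) or (N,1,H,W)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        feats, _ = self.encoder.forward(x, train)
        self._feature_maps = feats
        pooled = self.gap.forward(feats, train)
        self._features = pooled
        return self.head.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.gap.backward(d)
        self.encoder.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class-probability rows ``[p_normal, p_abnormal]``."""
        return softmax(self.forward(x, train=False).astype(np.float64))

    def feature_maps(self, x: np.ndarray) -> np.ndarray:
        """Deepest-convolution activation maps (N, C, h, w); used by Score-CAM."""
        self.forward(x, train=False)
        return self._feature_maps

    def gap_features(self, x: np.ndarray) -> np.ndarray:
        self.forward(x, train=False)
        return self._features

    def fingerprint(self) -> dict:
        return {
            "kind": "classifier",
            "width_multiplier": self.encoder.width_multiplier,
            "init_source": self.init_source,
        }

    def save(self, path: str | Path) -> None:
        save_checkpoint(self.fingerprint(), self.state_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "Classifier":
        fp, state = load_checkpoint(path)
        if fp.get("kind") != "classifier":
            raise ValueError(f"checkpoint is not a classifier: {fp}")
        encoder = VGGEncoder(1, fp["width_multiplier"], np.random.default_rng(0))
        model = cls(encoder, init_source=fp["init_source"])
        model.load_state_dict(state)
        return model


def build_classifier(
    encoder: VGGEncoder,
    init_source: str = "random",
    seed: int = 0,
) -> Classifier:
    """Attach a randomly initialized GAP + softmax head to an encoder."""
    return Classifier(encoder, init_source=init_source, seed=seed)


def _cohort_arrays(cohort: Cohort, split: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    recs = [r for r in cohort.records if r.split == split]
    if not recs:
        raise ValueError(f"no records in split {split!r}")
    x = np.stack([cohort.images[r.image_id].pixels for r in recs]).astype(np.float32)
    y = np.array([r.label for r in recs], dtype=np.int64)
    return x[:, None], y, [r.image_id for r in recs]


def fine_tune(
    classifier: Classifier,
    cohort: Cohort,
    config: ClassifierTrainConfig,
) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Fine-tune on the cohort's train/val splits with cross-entropy + SGD."""
    x_train, y_train, _ = _cohort_arrays(cohort, "train")
    x_val, y_val, _ = _cohort_arrays(cohort, "val")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single class")

    rng = np.random.default_rng(config.seed)
    head_opt = SGD(classifier.head.params(), lr=config.initial_lr)
    enc_opt = SGD(
        classifier.encoder.params(),
        lr=config.initial_lr * config.encoder_lr_scale,
    )
    sched = PlateauScheduler(config)
    history = TrainHistory()
    best_state: dict[str, np.ndarray] | None = None
    best_loss = np.inf

    n = x_train.shape[0]
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = classifier.forward(x_train[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            head_opt.zero_grad()
            enc_opt.zero_grad()
            classifier.backward(dlogits)
            head_opt.step()
            enc_opt.step()
            epoch_loss += loss
            n_batches += 1

        val_logits = _forward_in_batches(classifier, x_val, config.batch_size)
        val_loss, _ = softmax_cross_entropy(val_logits, y_val)
        history.train_loss.append(epoch_loss / n_batches)
        history.val_loss.append(val_loss)
        history.lr.append(head_opt.lr)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = classifier.state_dict()
        next_lr = sched.update(val_loss)
        head_opt.lr = next_lr
        enc_opt.lr = next_lr * config.encoder_lr_scale

    assert best_state is not None
    return best_state, history


def _forward_in_batches(
    classifier: Classifier, x: np.ndarray, batch_size: int
) -> np.ndarray:
    chunks = [
        classifier.forward(x[i : i + batch_size], train=False)
        for i in range(0, x.shape[0], batch_size)
    ]
    return np.concatenate(chunks, axis=0)


def predict_cohort(
    classifier: Classifier, cohort: Cohort, split: str, batch_size: int = 16
) -> pd.DataFrame:
    """Per-image probabilities and logits for one split."""
    x, y, ids = _cohort_arrays(cohort, split)
    logits = _forward_in_batches(classifier, x, batch_size)
    probs = softmax(logits.astype(np.float64))
    return pd.DataFrame(
        {
            "image_id": ids,
            "p_normal": probs[:, 0],
            "p_abnormal": probs[:, 1],
            "logit_normal": logits[:, 0],
            "logit_abnormal": logits[:, 1],
            "label": y,
        }
    )


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
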