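"""Classifier fusion: simple averaging, SLSQP-weighted averaging, and the
learnable attention-fuzzy combiner.

Simple averaging: elementwise mean of member probabilities.

SLSQP weighted averaging: minimizes the validation log-loss of the weighted
average probability ``sum_i w_i p_i(x)`` over the probability simplex
(``sum w_i = 1``, ``w_i >= 0``) with sequential least-squares programming
from a uniform start.

Attention-fuzzy (A-F): member backbones frozen; per-member GAP features are
concatenated and fed to a trainable dense attention layer whose softmax
produces per-member weights ``alpha_i``; member logits are combined as
``sum_i alpha_i f_i(x)``, multiplied by a trainable fuzziness scalar
``gamma`` (initialized to 1, unconstrained), and passed through a softmax.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from pretextnet._nnops import SGD, Dense, Param, softmax
from pretextnet.phantom import Cohort
from pretextnet.pretext import PlateauScheduler, TrainHistory
from pretextnet.transfer import Classifier, ClassifierTrainConfig, _cohort_arrays

__all__ = [
    "PredictionSet",
    "EnsembleWeights",
    "AFEnsembleModel",
    "simple_average",
    "fit_slsqp_weights",
    "apply_weights",
    "build_af_ensemble",
    "train_af_ensemble",
    "log_loss",
]

_PROB_FLOOR = 1e-12


@dataclass
class PredictionSet:
    """Aligned per-model probability and logit rows for one sample set."""

    model_names: list[str]
    probs: np.ndarray  # (n_models, n_samples, 2)
    logits: np.ndarray  # (n_models, n_samples, 2)
    labels: np.ndarray  # (n_samples,)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.logits = np.asarray(self.logits, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.probs.ndim != 3 or self.probs.shape[2] != 2:
            raise ValueError(f"probs must be (models, samples, 2), got {self.probs.shape}")
        if self.probs.shape != self.logits.shape:
            raise ValueError("probs and logits shapes differ")
        if len(self.model_names) != self.probs.shape[0]:
            raise ValueError("model_names length mismatch")
        if self.labels.shape[0] != self.probs.shape[1]:
            raise ValueError("labels do not cover the same samples")
        if not np.allclose(self.probs.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    @property
    def n_models(self) -> int:
        return self.probs.shape[0]


@dataclass
class EnsembleWeights:
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if np.any(self.w < -1e-9):
            raise ValueError("weights must be non-negative")
        if abs(self.w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        self.w = np.clip(self.w, 0.0, None)
        self.w = self.w / self.w.sum()


def log_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood with a 1e-12 probability floor."""
    p = np.clip(probs[np.arange(len(labels)), labels], _PROB_FLOOR, 1.0)
    return float(-np.mean(np.log(p)))


def simple_average(pred_set: PredictionSet) -> np.ndarray:
    """Elementwise mean of member probability rows."""
    if pred_set.n_models < 2:
        raise ValueError("need at least 2 members")
    return pred_set.probs.mean(axis=0)


def apply_weights(pred_set: PredictionSet, weights: EnsembleWeights) -> np.ndarray:
    """Convex combination ``sum_i w_i p_i(x)`` per sample."""
    if weights.w.shape[0] != pred_set.n_models:
        raise ValueError("weight vector length mismatch")
    return np.tensordot(weights.w, pred_set.probs, axes=(0, 0))


def fit_slsqp_weights(pred_set: PredictionSet) -> EnsembleWeights:
    """Simplex-constrained SLSQP minimization of the weighted-average log-loss.

    Starts from uniform weights; the result is guaranteed (by an explicit
    fallback) to be no worse than the uniform starting point.
    """
    if pred_set.n_models < 2:
        raise ValueError("need at least 2 members")
    n = pred_set.n_models
    labels = pred_set.labels

    def objective(w: np.ndarray) -> float:
        return log_loss(np.tensordot(w, pred_set.probs, axes=(0, 0)), labels)

    w0 = np.full(n, 1.0 / n)
    result = minimize(
        objective,
        w0,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
    )
    if not result.success and result.x is None:
        raise RuntimeError(f"SLSQP failed: {result.message}")
    w = np.clip(result.x, 0.0, None)
    total = w.sum()
    if total <= 0:
        w = w0
    else:
        w = w / total
    if objective(w) > objective(w0):  # safeguard: never worse than uniform
        w = w0
    return EnsembleWeights(w)


# ---------------------------------------------------------------------------
# attention-fuzzy ensemble


def _encoder_checksum(classifier: Classifier) -> str:
    h = hashlib.sha256()
    for name, param in sorted(classifier.encoder.named_params().items()):
        h.update(name.encode())
        h.update(param.value.tobytes())
    return h.hexdigest()


class AFEnsembleModel:
    """Attention-weighted, fuzziness-scaled softmax fusion of frozen members."""

    def __init__(self, members: Sequence[Classifier], seed: int = 0):
        if len(members) < 2:
            raise ValueError("need at least 2 member classifiers")
        dims = {m.feature_dim for m in members}
        if len(dims) != 1:
            raise ValueError("members have incompatible feature dimensions")
        self.members = list(members)
        self.frozen = True
        self._member_checksums = [_encoder_checksum(m) for m in self.members]
        rng = np.random.default_rng(seed)
        total_dim = sum(m.feature_dim for m in self.members)
        self.attention = Dense(total_dim, len(self.members), rng)
        # per-member logit layers start from the members' trained heads
        self.heads = []
        for m in self.members:
            head = Dense(m.feature_dim, 2, rng)
            head.W.value = m.head.W.value.copy()
            head.b.value = m.head.b.value.copy()
            self.heads.append(head)
        self.gamma = Param(np.array(1.0))
        self._cache = None

    def trainable_params(self) -> list[Param]:
        params = [self.attention.W, self.attention.b, self.gamma]
        for head in self.heads:
            params.extend([head.W, head.b])
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {
            "attention.W": self.attention.W.value.copy(),
            "attention.b": self.attention.b.value.copy(),
            "gamma": self.gamma.value.copy(),
        }
        for i, head in enumerate(self.heads):
            out[f"head{i}.W"] = head.W.value.copy()
            out[f"head{i}.b"] = head.b.value.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.attention.W.value = np.asarray(state["attention.W"], np.float32).copy()
        self.attention.b.value = np.asarray(state["attention.b"], np.float32).copy()
        self.gamma.value = np.asarray(state["gamma"], np.float32).copy()
        for i, head in enumerate(self.heads):
            head.W.value = np.asarray(state[f"head{i}.W"], np.float32).copy()
            head.b.value = np.asarray(state[f"head{i}.b"], np.float32).copy()

    def member_features(self, x: np.ndarray) -> list[np.ndarray]:
        """Per-member GAP features under the frozen backbones."""
        return [m.gap_features(x).astype(np.float64) for m in self.members]

    def forward_from_features(
        self, feats: Sequence[np.ndarray], train: bool = False
    ) -> np.ndarray:
        """Probability rows from precomputed per-member GAP features."""
        concat = np.concatenate(feats, axis=1)
        scores = concat @ self.attention.W.value + self.attention.b.value
        alphas = softmax(scores)  # (n_samples, n_members)
        member_logits = [
            f @ h.W.value + h.b.value for f, h in zip(feats, self.heads)
        ]
        combined = sum(
            alphas[:, i : i + 1] * member_logits[i] for i in range(len(self.members))
        )
        z = float(self.gamma.value) * combined
        probs = softmax(z)
        if train:
            self._cache = (feats, concat, alphas, member_logits, combined)
        return probs

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.forward_from_features(self.member_features(x))

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        concat = np.concatenate(self.member_features(x), axis=1)
        return softmax(concat @ self.attention.W.value + self.attention.b.value)

    def backward(self, dz: np.ndarray) -> None:
        """Gradients w.r.t. attention, logit heads, and gamma only."""
        feats, concat, alphas, member_logits, combined = self._cache
        gamma = float(self.gamma.value)
        self.gamma.grad += np.float32(np.sum(dz * combined))
        dcombined = gamma * dz
        dalpha = np.zeros_like(alphas)
        for i, (f, head) in enumerate(zip(feats, self.heads)):
            df_i = alphas[:, i : i + 1] * dcombined
            head.W.grad += (f.T @ df_i).astype(np.float32)
            head.b.grad += df_i.sum(axis=0).astype(np.float32)
            dalpha[:, i] = np.sum(dcombined * member_logits[i], axis=1)
        # softmax jacobian for the attention scores
        dscores = alphas * (dalpha - np.sum(alphas * dalpha, axis=1, keepdims=True))
        self.attention.W.grad += (concat.T @ dscores).astype(np.float32)
        self.attention.b.grad += dscores.sum(axis=0).astype(np.float32)
        self._cache = None

    def verify_frozen(self) -> None:
        current = [_encoder_checksum(m) for m in self.members]
        if current != self._member_checksums:
            raise RuntimeError("member backbone weights changed: members not frozen")


def build_af_ensemble(
    members: Sequence[Classifier], seed: int = 0
) -> AFEnsembleModel:
    """Wire frozen member classifiers into an attention-fuzzy ensemble."""
    return AFEnsembleModel(members, seed=seed)


def train_af_ensemble(
    af_model: AFEnsembleModel,
    cohort: Cohort,
    config: ClassifierTrainConfig,
) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Train only the attention layer, logit heads, and gamma (members frozen)."""
    if not af_model.frozen:
        raise RuntimeError("member backbones must be frozen before training")
    x_train, y_train, _ = _cohort_arrays(cohort, "train")
    x_val, y_val, _ = _cohort_arrays(cohort, "val")

    # backbones are frozen, so features can be computed once
    feats_train = af_model.member_features(x_train)
    feats_val = af_model.member_features(x_val)

    rng = np.random.default_rng(config.seed)
    opt = SGD(af_model.trainable_params(), lr=config.initial_lr)
    sched = PlateauScheduler(config)
    history = TrainHistory()
    best_state, best_loss = None, np.inf

    n = x_train.shape[0]
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_feats = [f[idx] for f in feats_train]
            probs = af_model.forward_from_features(batch_feats, train=True)
            # cross-entropy gradient w.r.t. the pre-softmax combined logits
            grad = probs.copy()
            grad[np.arange(len(idx)), y_train[idx]] -= 1.0
            loss = log_loss(probs, y_train[idx])
            opt.zero_grad()
            af_model.backward(grad / len(idx))
            opt.step()
            epoch_loss += loss
            n_batches += 1

        val_probs = af_model.forward_from_features(feats_val)
        val_loss = log_loss(val_probs, y_val)
        history.train_loss.append(epoch_loss / n_batches)
        history.val_loss.append(val_loss)
        history.lr.append(opt.lr)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = af_model.state_dict()
        opt.lr = sched.update(val_loss)

    af_model.verify_frozen()
    assert best_state is not None
    return best_state, history
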