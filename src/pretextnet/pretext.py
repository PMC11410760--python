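"""Pretext training of the restorer on degraded/clean pairs with SSIM loss.

The regimen: Adam from a 1e-3 learning rate; when the validation loss stops
improving for 10 consecutive epochs the rate is halved, never dropping
below 1e-6; only the weights achieving the lowest validation loss are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pretextnet import iqa
from pretextnet._nnops import Adam
from pretextnet.degrade import PairedSample
from pretextnet.sharp_unet import Restorer

__all__ = [
    "PretextTrainConfig",
    "TrainHistory",
    "ssim_loss",
    "schedule_lr",
    "train_pretext",
    "PlateauScheduler",
]


@dataclass
class PretextTrainConfig:
    initial_lr: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    lr_floor: float = 1e-6
    max_epochs: int = 100
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.lr_floor >= self.initial_lr:
            raise ValueError("lr_floor must be below initial_lr")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        if not self.val_loss:
            raise ValueError("empty history")
        return int(np.argmin(self.val_loss))

    def __len__(self) -> int:
        return len(self.val_loss)


def ssim_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """``1 - mean SSIM`` over a batch; zero iff the batches are identical."""
    loss, _ = _ssim_loss_and_grad(pred, target, want_grad=False)
    return loss


def _ssim_loss_and_grad(
    pred: np.ndarray, target: np.ndarray, want_grad: bool = True
) -> tuple[float, np.ndarray | None]:
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.ndim == 2:
        pred, target = pred[None], target[None]
    if pred.ndim == 4:  # NCHW with a single channel
        pred, target = pred[:, 0], target[:, 0]
    n = pred.shape[0]
    total = 0.0
    grads = np.zeros(pred.shape) if want_grad else None
    for i in range(n):
        if want_grad:
            s, g = iqa.ssim_with_gradient(pred[i], target[i])
            grads[i] = -g / n
        else:
            s = iqa.ssim(pred[i], target[i])
        total += s
    return 1.0 - total / n, grads


class PlateauScheduler:
    """Reduce-on-plateau: halve after ``patience`` epochs without improvement."""

    def __init__(self, config: PretextTrainConfig):
        self.cfg = config
        self.lr = config.initial_lr
        self.best = np.inf
        self.wait = 0

    def update(self, val_loss: float) -> float:
        """Record one epoch's validation loss; returns the lr for the next epoch."""
        if val_loss < self.best:
            self.best = val_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.cfg.plateau_patience:
                self.lr = max(self.lr * self.cfg.plateau_factor, self.cfg.lr_floor)
                self.wait = 0
        return self.lr


def schedule_lr(history: TrainHistory | Sequence[float], config: PretextTrainConfig) -> float:
    """Next learning rate implied by a validation-loss history (pure replay)."""
    losses = history.val_loss if isinstance(history, TrainHistory) else list(history)
    if len(losses) == 0:
        raise ValueError("need at least one recorded epoch")
    sched = PlateauScheduler(config)
    for loss in losses:
        lr = sched.update(loss)
    return lr


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _stack(pairs: Sequence[PairedSample], idx, member: str) -> np.ndarray:
    return np.stack(
        [getattr(pairs[i], member).pixels for i in idx], axis=0
    ).astype(np.float32)[:, None]


def train_pretext(
    model: Restorer,
    train_pairs: Sequence[PairedSample],
    val_pairs: Sequence[PairedSample],
    config: PretextTrainConfig,
) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Train the restorer; returns the best-validation weights and history."""
    if len(train_pairs) == 0 or len(val_pairs) == 0:
        raise ValueError("train and val pair sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.initial_lr)
    sched = PlateauScheduler(config)
    history = TrainHistory()
    best_state: dict[str, np.ndarray] | None = None
    best_loss = np.inf

    for _ in range(config.max_epochs):
        epoch_loss = 0.0
        n_batches = 0
        for idx in _batches(len(train_pairs), config.batch_size, rng):
            x = _stack(train_pairs, idx, "degraded")
            y = _stack(train_pairs, idx, "clean")
            pred = model.forward(x, train=True)
            loss, dpred = _ssim_loss_and_grad(pred, y)
            opt.zero_grad()
            model.backward(dpred[:, None].astype(np.float32))
            opt.step()
            epoch_loss += loss
            n_batches += 1

        val_loss, metrics = _evaluate(model, val_pairs, config.batch_size)
        history.train_loss.append(epoch_loss / n_batches)
        history.val_loss.append(val_loss)
        history.lr.append(opt.lr)
        history.val_ssim.append(metrics["ssim"])
        history.val_psnr.append(metrics["psnr"])
        history.val_mse.append(metrics["mse"])
        history.val_mae.append(metrics["mae"])

        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
        opt.lr = sched.update(val_loss)

    assert best_state is not None
    return best_state, history


def _evaluate(
    model: Restorer, pairs: Sequence[PairedSample], batch_size: int
) -> tuple[float, dict[str, float]]:
    losses, ssims, psnrs, mses, maes = [], [], [], [], []
    for start in range(0, len(pairs), batch_size):
        idx = range(start, min(start + batch_size, len(pairs)))
        x = _stack(pairs, idx, "degraded")
        y = _stack(pairs, idx, "clean")
        pred = model.forward(x, train=False)
        for i in range(pred.shape[0]):
            p, t = pred[i, 0].astype(np.float64), y[i, 0].astype(np.float64)
            s = iqa.ssim(p, t)
            ssims.append(s)
            losses.append(1.0 - s)
            psnrs.append(iqa.psnr(t, p))
            mses.append(iqa.mse(t, p))
            maes.append(iqa.mae(t, p))
    finite_psnr = [p for p in psnrs if np.isfinite(p)]
    return float(np.mean(losses)), {
        "ssim": float(np.mean(ssims)),
        "psnr": float(np.mean(finite_psnr)) if finite_psnr else float("inf"),
        "mse": float(np.mean(mses)),
        "mae": float(np.mean(maes)),
    }
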