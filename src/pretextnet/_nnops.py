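"""Minimal NumPy layer library with explicit forward/backward passes.

Internal support code for the restorer, classifier, and ensemble models.
Arrays are NCHW float32. Each layer caches what its backward pass needs;
layers are therefore stateful per forward call and not re-entrant.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2x2",
    "MaxPool2x2",
    "ReLU",
    "Sigmoid",
    "Dense",
    "GlobalAvgPool",
    "SharpenDepthwise",
    "SHARPEN_KERNEL",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
    "Adam",
]

SHARPEN_KERNEL = np.array(
    [[0.0, -1.0, 0.0], [-1.0, 5.0, -1.0], [0.0, -1.0, 0.0]], dtype=np.float32
)


class Param:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _he_std(fan_in: int) -> float:
    return float(np.sqrt(2.0 / fan_in))


def _im2col3(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patches of (N,C,H,W) as rows (N*H*W, C*9)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    return np.ascontiguousarray(cols)


class Conv2d:
    """3x3 convolution, stride 1, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(rng.normal(0.0, _he_std(c_in * 9), (c_out, c_in, 3, 3)))
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        out = cols @ self.W.value.reshape(self.c_out, -1).T + self.b.value
        if train:
            self._cols, self._shape = cols, x.shape
        else:
            self._cols = None
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dymat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.W.grad += (dymat.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dymat.sum(axis=0)
        # dx = same-conv of dy with the flipped, channel-transposed kernel
        w_flip = self.W.value.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        cols_dy = _im2col3(dy)
        dx = cols_dy @ w_flip.reshape(self.c_in, -1).T
        self._cols = None
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class ConvTranspose2x2:
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(rng.normal(0.0, _he_std(c_in * 4), (c_in, c_out, 2, 2)))
        self.b = Param(np.zeros(c_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        y = np.einsum("nchw,cfij->nfhiwj", x, self.W.value, optimize=True)
        y = y.reshape(n, self.c_out, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        self._x = x if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, f, h2, w2 = dy.shape
        dyr = dy.reshape(n, f, h2 // 2, 2, w2 // 2, 2)
        self.W.grad += np.einsum("nchw,nfhiwj->cfij", self._x, dyr, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nfhiwj,cfij->nchw", dyr, self.W.value, optimize=True)
        self._x = None
        return dx


class MaxPool2x2:
    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dz = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dz, self._idx[..., None], dy[..., None], axis=-1)
        dx = (
            dz.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._idx = None
        return dx


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Sigmoid:
    def __init__(self) -> None:
        self._y: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._y * (1.0 - self._y)
        self._y = None
        return dx


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, _he_std(d_in), (d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.W.value.T
        self._x = None
        return dx


class GlobalAvgPool:
    """Spatial mean per channel: (N,C,H,W) -> (N,C)."""

    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class SharpenDepthwise:
    """Fixed depth-wise 3x3 sharpening with reflective (edge) borders.

    The kernel ``[[0,-1,0],[-1,5,-1],[0,-1,0]]`` sums to 1 and adds no
    learnable parameters; each channel is convolved independently.
    """

    def params(self) -> list[Param]:
        return []

    @staticmethod
    def forward(x: np.ndarray, train: bool = True) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")
        return (
            5.0 * x
            - xp[:, :, :-2, 1:-1]
            - xp[:, :, 2:, 1:-1]
            - xp[:, :, 1:-1, :-2]
            - xp[:, :, 1:-1, 2:]
        )

    @staticmethod
    def backward(dy: np.ndarray) -> np.ndarray:
        # adjoint of the edge-clamped shift stencil
        dx = 5.0 * dy
        up = np.zeros_like(dy)  # adjoint of "take from row above"
        up[:, :, 0, :] = dy[:, :, 0, :] + dy[:, :, 1, :]
        up[:, :, 1:-1, :] += dy[:, :, 2:, :]
        down = np.zeros_like(dy)
        down[:, :, -1, :] = dy[:, :, -1, :] + dy[:, :, -2, :]
        down[:, :, 1:-1, :] += dy[:, :, :-2, :]
        left = np.zeros_like(dy)
        left[:, :, :, 0] = dy[:, :, :, 0] + dy[:, :, :, 1]
        left[:, :, :, 1:-1] += dy[:, :, :, 2:]
        right = np.zeros_like(dy)
        right[:, :, :, -1] = dy[:, :, :, -1] + dy[:, :, :, -2]
        right[:, :, :, 1:-1] += dy[:, :, :, :-2]
        return dx - up - down - left - right


# ---------------------------------------------------------------------------
# losses and optimizers


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class SGD:
    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
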