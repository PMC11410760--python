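"""The sharpening-skip U-Net restoration architecture.

A VGG-16 encoder (blocks of 2/2/3/3/3 3x3 convolutions with 64/128/256/512/
512 filters, 2x2 max pooling after the first four blocks) feeds a mirrored
decoder (2x2 up-convolution followed by 3/3/2/2 3x3 convolutions per block).
Skip connections from encoder blocks 1-4 pass through a fixed depth-wise
sharpening convolution before concatenation; sharpening introduces no
learnable parameters. The head is one 3x3 convolution with a sigmoid,
mapping (h, w, 1) -> (h, w, 1) in (0, 1).

A ``width_multiplier`` scales all filter counts for desk-scale runs; the
default of 1.0 is the full-size architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pretextnet._nnops import (
    SHARPEN_KERNEL,
    Conv2d,
    ConvTranspose2x2,
    MaxPool2x2,
    Param,
    ReLU,
    SharpenDepthwise,
    Sigmoid,
)

__all__ = [
    "EncoderSpec",
    "SharpKernel",
    "VGGEncoder",
    "Restorer",
    "build_restorer",
    "sharpen_features",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

BASE_FILTERS = (64, 128, 256, 512, 512)
ENCODER_CONV_COUNTS = (2, 2, 3, 3, 3)
DECODER_CONV_COUNTS = (3, 3, 2, 2)


@dataclass(frozen=True)
class EncoderSpec:
    block_conv_counts: tuple[int, ...] = ENCODER_CONV_COUNTS
    block_filters: tuple[int, ...] = BASE_FILTERS
    conv_kernel: tuple[int, int] = (3, 3)
    activation: str = "relu"


@dataclass(frozen=True)
class SharpKernel:
    coefficients: np.ndarray = field(default_factory=lambda: SHARPEN_KERNEL.copy())


def sharpen_features(features: np.ndarray) -> np.ndarray:
    """Depth-wise sharpening of multi-channel 2-D feature maps.

    Accepts ``(C, H, W)`` or ``(N, C, H, W)``; returns the same shape.
    """
    arr = np.asarray(features)
    if arr.ndim == 3:
        return SharpenDepthwise.forward(arr[None])[0]
    if arr.ndim == 4:
        return SharpenDepthwise.forward(arr)
    raise ValueError(f"expected 3-D or 4-D features, got shape {arr.shape}")


def _scaled_filters(width_multiplier: float) -> tuple[int, ...]:
    if width_multiplier <= 0:
        raise ValueError("width_multiplier must be positive")
    return tuple(max(1, int(round(f * width_multiplier))) for f in BASE_FILTERS)


class VGGEncoder:
    """Five-block VGG-16 convolutional encoder (shared by restorer and classifier)."""

    def __init__(
        self,
        in_channels: int = 1,
        width_multiplier: float = 1.0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.width_multiplier = width_multiplier
        self.filters = _scaled_filters(width_multiplier)
        self.blocks: list[list[tuple[Conv2d, ReLU]]] = []
        c_prev = in_channels
        for n_convs, f in zip(ENCODER_CONV_COUNTS, self.filters):
            block = []
            for _ in range(n_convs):
                block.append((Conv2d(c_prev, f, rng), ReLU()))
                c_prev = f
            self.blocks.append(block)
        self.pools = [MaxPool2x2() for _ in range(4)]

    def named_params(self, prefix: str = "enc") -> dict[str, Param]:
        out: dict[str, Param] = {}
        for b, block in enumerate(self.blocks):
            for j, (conv, _) in enumerate(block):
                out[f"{prefix}.b{b}.conv{j}.W"] = conv.W
                out[f"{prefix}.b{b}.conv{j}.b"] = conv.b
        return out

    def params(self) -> list[Param]:
        return list(self.named_params().values())

    def forward(
        self, x: np.ndarray, train: bool = True
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Returns the block-5 activation and the four pre-pool skip tensors."""
        skips: list[np.ndarray] = []
        for b, block in enumerate(self.blocks):
            for conv, relu in block:
                x = relu.forward(conv.forward(x, train), train)
            if b < 4:
                skips.append(x)
                x = self.pools[b].forward(x, train)
        return x, skips

    def backward(
        self, d_bottom: np.ndarray, d_skips: list[np.ndarray] | None = None
    ) -> np.ndarray:
        d = d_bottom
        for b in range(4, -1, -1):
            for conv, relu in reversed(self.blocks[b]):
                d = conv.backward(relu.backward(d))
            if b > 0:
                d = self.pools[b - 1].backward(d)
                if d_skips is not None and d_skips[b - 1] is not None:
                    d = d + d_skips[b - 1]
        return d


class Restorer:
    """Encoder-decoder restorer with sharpening skip connections."""

    def __init__(
        self,
        input_size: tuple[int, int] = (224, 224),
        width_multiplier: float = 1.0,
        use_sharpening: bool = True,
        seed: int = 0,
    ):
        h, w = input_size
        if h % 16 != 0 or w % 16 != 0:
            raise ValueError(
                f"input size {input_size} must be divisible by 16 (four poolings)"
            )
        self.input_size = (int(h), int(w))
        self.width_multiplier = width_multiplier
        self.use_sharpening = use_sharpening
        self.seed = seed
        rng = np.random.default_rng(seed)

        self.encoder = VGGEncoder(1, width_multiplier, rng)
        f = self.encoder.filters
        dec_widths = (f[3], f[2], f[1], f[0])
        up_in = (f[4], f[3], f[2], f[1])

        self.upconvs: list[ConvTranspose2x2] = []
        self.dec_blocks: list[list[tuple[Conv2d, ReLU]]] = []
        for i in range(4):
            fd = dec_widths[i]
            self.upconvs.append(ConvTranspose2x2(up_in[i], fd, rng))
            block = []
            c_prev = 2 * fd  # sharpened skip (fd) + up-sampled features (fd)
            for _ in range(DECODER_CONV_COUNTS[i]):
                block.append((Conv2d(c_prev, fd, rng), ReLU()))
                c_prev = fd
            self.dec_blocks.append(block)
        self.head = Conv2d(f[0], 1, rng)
        self.out_act = Sigmoid()
        self._skip_widths = (f[0], f[1], f[2], f[3])

    # -- parameter bookkeeping ------------------------------------------------

    def named_params(self) -> dict[str, Param]:
        out = self.encoder.named_params("enc")
        for i, up in enumerate(self.upconvs):
            out[f"dec.up{i}.W"] = up.W
            out[f"dec.up{i}.b"] = up.b
        for i, block in enumerate(self.dec_blocks):
            for j, (conv, _) in enumerate(block):
                out[f"dec.d{i}.conv{j}.W"] = conv.W
                out[f"dec.d{i}.conv{j}.b"] = conv.b
        out["head.W"] = self.head.W
        out["head.b"] = self.head.b
        return out

    def params(self) -> list[Param]:
        return list(self.named_params().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.named_params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        for k, p in params.items():
            if p.value.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.value = np.asarray(state[k], dtype=np.float32).copy()

    def fingerprint(self) -> dict:
        return {
            "kind": "restorer",
            "input_size": list(self.input_size),
            "width_multiplier": self.width_multiplier,
            "use_sharpening": self.use_sharpening,
        }

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        bottom, skips = self.encoder.forward(x, train)
        self._bottom_activation = bottom
        d = bottom
        for i in range(4):
            d = self.upconvs[i].forward(d, train)
            s = skips[3 - i]
            ss = SharpenDepthwise.forward(s) if self.use_sharpening else s
            d = np.concatenate([ss, d], axis=1)
            for conv, relu in self.dec_blocks[i]:
                d = relu.forward(conv.forward(d, train), train)
        return self.out_act.forward(self.head.forward(d, train), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head.backward(self.out_act.backward(dout))
        d_skips: list[np.ndarray | None] = [None] * 4
        for i in range(3, -1, -1):
            for conv, relu in reversed(self.dec_blocks[i]):
                d = conv.backward(relu.backward(d))
            f_skip = self._skip_widths[3 - i]
            d_skip, d_up = d[:, :f_skip], d[:, f_skip:]
            d_skips[3 - i] = (
                SharpenDepthwise.backward(d_skip) if self.use_sharpening else d_skip
            )
            d = self.upconvs[i].backward(np.ascontiguousarray(d_up))
        return self.encoder.backward(d, d_skips)

    def restore(self, x: np.ndarray) -> np.ndarray:
        """Inference forward pass without caching."""
        return self.forward(x, train=False)

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        save_checkpoint(self.fingerprint(), self.state_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "Restorer":
        fp, state = load_checkpoint(path)
        if fp.get("kind") != "restorer":
            raise ValueError(f"checkpoint is not a restorer: {fp}")
        model = cls(
            input_size=tuple(fp["input_size"]),
            width_multiplier=fp["width_multiplier"],
            use_sharpening=fp["use_sharpening"],
        )
        model.load_state_dict(state)
        return model


def build_restorer(
    input_size: tuple[int, int],
    width_multiplier: float = 1.0,
    use_sharpening: bool = True,
    seed: int = 0,
) -> Restorer:
    """Construct a randomly initialized restorer for the given input size."""
    return Restorer(input_size, width_multiplier, use_sharpening, seed)


def count_parameters(model) -> int:
    """Total number of learnable scalars (weights + biases)."""
    return int(sum(p.value.size for p in model.params()))


def save_checkpoint(
    fingerprint: dict, state: dict[str, np.ndarray], path: str | Path
) -> None:
    arrays = {f"param/{k}": v for k, v in state.items()}
    with open(path, "wb") as fh:
        np.savez(fh, __fingerprint__=np.bytes_(json.dumps(fingerprint)), **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such checkpoint: {path}")
    with np.load(path, allow_pickle=False) as data:
        fp = json.loads(bytes(data["__fingerprint__"]).decode())
        state = {
            k[len("param/") :]: data[k] for k in data.files if k.startswith("param/")
        }
    return fp, state
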