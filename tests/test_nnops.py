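"""Gradient and adjoint checks for the internal layer library."""

import numpy as np
import pytest

from pretextnet._nnops import (
    SHARPEN_KERNEL,
    Adam,
    Conv2d,
    ConvTranspose2x2,
    Dense,
    GlobalAvgPool,
    MaxPool2x2,
    Param,
    ReLU,
    SharpenDepthwise,
    Sigmoid,
    softmax,
    softmax_cross_entropy,
)
from conftest import finite_difference_grad


def _proj_loss(out, R):
    return float(np.sum(out * R))


@pytest.fixture
def rng():
    return np.random.default_rng(99)


class TestConv2d:
    def test_input_gradient(self, rng):
        layer = Conv2d(3, 4, rng)
        x = rng.standard_normal((2, 3, 6, 6)).astype(np.float32)
        R = rng.standard_normal((2, 4, 6, 6)).astype(np.float32)
        out = layer.forward(x)
        dx = layer.backward(R)
        fd = finite_difference_grad(
            lambda xv: _proj_loss(layer.forward(xv.astype(np.float32), train=False), R),
            x,
            eps=1e-2,
        )
        assert np.allclose(dx, fd, rtol=1e-2, atol=1e-2)

    def test_weight_gradient(self, rng):
        layer = Conv2d(2, 3, rng)
        x = rng.standard_normal((1, 2, 5, 5)).astype(np.float32)
        R = rng.standard_normal((1, 3, 5, 5)).astype(np.float32)
        layer.forward(x)
        layer.backward(R)
        w0 = layer.W.value.copy()

        def loss_of_w(wv):
            layer.W.value = wv.astype(np.float32)
            val = _proj_loss(layer.forward(x, train=False), R)
            layer.W.value = w0
            return val

        fd = finite_difference_grad(loss_of_w, w0, eps=1e-2)
        assert np.allclose(layer.W.grad, fd, rtol=1e-2, atol=1e-2)


class TestConvTranspose:
    def test_shapes_and_gradient(self, rng):
        layer = ConvTranspose2x2(3, 2, rng)
        x = rng.standard_normal((2, 3, 4, 4)).astype(np.float32)
        out = layer.forward(x)
        assert out.shape == (2, 2, 8, 8)
        R = rng.standard_normal(out.shape).astype(np.float32)
        dx = layer.backward(R)
        fd = finite_difference_grad(
            lambda xv: _proj_loss(layer.forward(xv.astype(np.float32), train=False), R),
            x,
            eps=1e-2,
        )
        assert np.allclose(dx, fd, rtol=1e-2, atol=1e-2)


class TestMaxPool:
    def test_forward_and_gradient(self, rng):
        layer = MaxPool2x2()
        # keep entries well separated so finite differences don't flip the max
        x = (rng.permutation(64).reshape(1, 1, 8, 8) * 0.5).astype(np.float32)
        out = layer.forward(x)
        assert out.shape == (1, 1, 4, 4)
        R = rng.standard_normal(out.shape).astype(np.float32)
        dx = layer.backward(R)
        fd = finite_difference_grad(
            lambda xv: _proj_loss(layer.forward(xv.astype(np.float32), train=False), R),
            x,
            eps=1e-2,
        )
        assert np.allclose(dx, fd, atol=1e-2)


class TestDenseGapActivations:
    def test_dense_gradient(self, rng):
        layer = Dense(5, 3, rng)
        x = rng.standard_normal((4, 5)).astype(np.float32)
        R = rng.standard_normal((4, 3)).astype(np.float32)
        layer.forward(x)
        dx = layer.backward(R)
        assert np.allclose(dx, R @ layer.W.value.T, atol=1e-5)
        assert np.allclose(layer.W.grad, x.T @ R, atol=1e-4)

    def test_gap_gradient(self, rng):
        layer = GlobalAvgPool()
        x = rng.standard_normal((2, 3, 4, 4)).astype(np.float32)
        out = layer.forward(x)
        assert np.allclose(out, x.mean(axis=(2, 3)))
        dx = layer.backward(np.ones((2, 3), dtype=np.float32))
        assert np.allclose(dx, 1 / 16)

    def test_relu_and_sigmoid_gradients(self, rng):
        x = rng.standard_normal((3, 7)).astype(np.float32) + 0.05
        relu = ReLU()
        out = relu.forward(x)
        assert np.allclose(relu.backward(np.ones_like(out)), (x > 0).astype(float))
        sig = Sigmoid()
        y = sig.forward(x)
        assert np.allclose(sig.backward(np.ones_like(y)), y * (1 - y), atol=1e-6)


class TestSharpen:
    def test_constant_unchanged(self):
        x = np.full((1, 2, 6, 6), 0.7, dtype=np.float32)
        assert np.allclose(SharpenDepthwise.forward(x), x)

    def test_impulse_stamps_kernel(self):
        x = np.zeros((1, 1, 7, 7), dtype=np.float32)
        x[0, 0, 3, 3] = 1.0
        out = SharpenDepthwise.forward(x)
        assert np.allclose(out[0, 0, 2:5, 2:5], SHARPEN_KERNEL)
        assert np.allclose(out[0, 0, :2], 0.0)

    def test_linear_ramp_interior_unchanged(self):
        rr, cc = np.mgrid[0:8, 0:8].astype(np.float32)
        x = (0.3 * rr + 0.2 * cc)[None, None]
        out = SharpenDepthwise.forward(x)
        assert np.allclose(out[0, 0, 1:-1, 1:-1], x[0, 0, 1:-1, 1:-1], atol=1e-5)

    def test_kernel_sums_to_one_with_center_five(self):
        assert SHARPEN_KERNEL.sum() == 1.0
        assert SHARPEN_KERNEL[1, 1] == 5.0

    def test_adjoint_identity(self, rng):
        # <A x, y> == <x, A^T y> must hold exactly for the linear operator
        x = rng.standard_normal((2, 3, 6, 5)).astype(np.float64)
        y = rng.standard_normal((2, 3, 6, 5)).astype(np.float64)
        lhs = np.sum(SharpenDepthwise.forward(x) * y)
        rhs = np.sum(x * SharpenDepthwise.backward(y))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestSoftmaxCrossEntropy:
    def test_probabilities_normalized(self, rng):
        logits = rng.standard_normal((10, 2))
        p = softmax(logits)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_gradient_matches_finite_difference(self, rng):
        logits = rng.standard_normal((5, 2))
        labels = np.array([0, 1, 1, 0, 1])
        _, grad = softmax_cross_entropy(logits, labels)
        fd = finite_difference_grad(
            lambda lv: softmax_cross_entropy(lv, labels)[0], logits, eps=1e-5
        )
        assert np.allclose(grad, fd, atol=1e-6)


class TestOptimizers:
    def test_sgd_step(self):
        p = Param(np.array([1.0, 2.0]))
        p.grad[:] = [0.5, -0.5]
        from pretextnet._nnops import SGD

        SGD([p], lr=0.1).step()
        assert np.allclose(p.value, [0.95, 2.05])

    def test_adam_reduces_quadratic(self):
        p = Param(np.array([5.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            p.grad[:] = 2 * p.value
            opt.step()
        assert abs(float(p.value[0])) < 0.1
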