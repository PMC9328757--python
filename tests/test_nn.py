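"""Numerical correctness of the layer library: every analytic gradient is
checked against central finite differences on small tensors, and the
convolutions against a brute-force spatial oracle."""

import numpy as np
import pytest

from shootseg.nn import (
    Adam,
    BatchNorm2D,
    Conv2D,
    ConvTranspose2D,
    MaxPool2D,
    ReLU,
    Sigmoid,
)
from shootseg.nn import functional as F

RNG = np.random.default_rng(123)


def brute_conv(x, w, b):
    """Direct same-padded correlation (the oracle the FFT path must match)."""
    n, h, wd, ci = x.shape
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x.astype(np.float64), ((0, 0), (p, p), (p, p), (0, 0)))
    y = np.zeros((n, h, wd, w.shape[3]))
    for a in range(k):
        for bb in range(k):
            y += xp[:, a : a + h, bb : bb + wd, :] @ w[a, bb].astype(np.float64)
    return y + b


@pytest.mark.parametrize("shape,k", [((2, 9, 11, 3), 7), ((1, 8, 8, 2), 3), ((2, 5, 5, 4), 1)])
def test_conv_forward_matches_bruteforce(shape, k):
    x = RNG.standard_normal(shape).astype(np.float32)
    w = RNG.standard_normal((k, k, shape[3], 4)).astype(np.float32)
    b = RNG.standard_normal(4).astype(np.float32)
    y = F.conv2d_forward(x, w, b)
    np.testing.assert_allclose(y, brute_conv(x, w, b), rtol=2e-4, atol=2e-4)


def _numeric_grad(f, arr, idx, eps=1e-3):
    plus, minus = arr.copy(), arr.copy()
    plus[idx] += eps
    minus[idx] -= eps
    return (f(plus) - f(minus)) / (2 * eps)


def test_conv_backward_matches_numeric_gradients():
    x = RNG.standard_normal((2, 7, 6, 3)).astype(np.float32)
    w = RNG.standard_normal((7, 7, 3, 2)).astype(np.float32)
    b = np.zeros(2, dtype=np.float32)
    dy = RNG.standard_normal((2, 7, 6, 2)).astype(np.float32)
    _, xs, fs = F.conv2d_forward(x, w, b, return_spectrum=True)
    dx, dw, db = F.conv2d_backward(xs, fs, x, w, dy)
    for _ in range(8):
        ix = tuple(RNG.integers(0, s) for s in x.shape)
        num = _numeric_grad(lambda a: float((brute_conv(a, w, b) * dy).sum()), x, ix)
        assert dx[ix] == pytest.approx(num, rel=2e-2, abs=2e-3)
    for _ in range(8):
        iw = tuple(RNG.integers(0, s) for s in w.shape)
        num = _numeric_grad(lambda a: float((brute_conv(x, a, b) * dy).sum()), w, iw)
        assert dw[iw] == pytest.approx(num, rel=2e-2, abs=2e-3)
    np.testing.assert_allclose(db, dy.sum(axis=(0, 1, 2)), rtol=1e-4)


def test_transpose_conv_shape_and_adjoint_identity():
    """A transpose convolution is the adjoint of a strided convolution:
    <y, T(x)> must equal <T*(y), x> with T* its backward-data map."""
    x = RNG.standard_normal((2, 5, 6, 3)).astype(np.float32)
    w = RNG.standard_normal((3, 3, 3, 4)).astype(np.float32)
    b = np.zeros(4, dtype=np.float32)
    y = F.conv_transpose2d_forward(x, w, b)
    assert y.shape == (2, 10, 12, 4)
    v = RNG.standard_normal(y.shape).astype(np.float32)
    dx, _, _ = F.conv_transpose2d_backward(x, w, v)
    assert float((y * v).sum()) == pytest.approx(float((dx * x).sum()), rel=1e-3)


def test_transpose_conv_weight_gradient_numeric():
    x = RNG.standard_normal((1, 4, 4, 2)).astype(np.float32)
    w = RNG.standard_normal((3, 3, 2, 3)).astype(np.float32)
    b = np.zeros(3, dtype=np.float32)
    dy = RNG.standard_normal((1, 8, 8, 3)).astype(np.float32)
    _, dw, _ = F.conv_transpose2d_backward(x, w, dy)
    for _ in range(8):
        iw = tuple(RNG.integers(0, s) for s in w.shape)
        num = _numeric_grad(
            lambda a: float((F.conv_transpose2d_forward(x, a, b) * dy).sum()), w, iw
        )
        assert dw[iw] == pytest.approx(num, rel=2e-2, abs=2e-3)


def test_batchnorm_normalizes_and_gradients_check():
    bn = BatchNorm2D(3)
    x = (RNG.standard_normal((4, 5, 5, 3)) * 3 + 2).astype(np.float32)
    y = bn.forward(x, training=True)
    np.testing.assert_allclose(y.mean(axis=(0, 1, 2)), 0.0, atol=1e-4)
    np.testing.assert_allclose(y.std(axis=(0, 1, 2)), 1.0, atol=1e-3)

    dy = RNG.standard_normal(y.shape).astype(np.float32)
    bn.forward(x, training=True)
    dx = bn.backward(dy)

    def loss(arr):
        fresh = BatchNorm2D(3)
        return float((fresh.forward(arr, training=True) * dy).sum())

    for _ in range(6):
        ix = tuple(RNG.integers(0, s) for s in x.shape)
        num = _numeric_grad(loss, x, ix, eps=1e-2)
        assert dx[ix] == pytest.approx(num, rel=5e-2, abs=5e-3)


def test_maxpool_halves_size_and_routes_gradient():
    x = np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1)
    pool = MaxPool2D()
    y = pool.forward(x, training=True)
    assert y.shape == (1, 2, 2, 1)
    np.testing.assert_array_equal(y[0, :, :, 0], [[5, 7], [13, 15]])
    dx = pool.backward(np.ones_like(y))
    assert dx.sum() == 4.0  # one unit of gradient per pooled window
    assert dx[0, 1, 1, 0] == 1.0  # at the argmax position


def test_relu_and_sigmoid_shapes_and_ranges():
    x = RNG.standard_normal((2, 4, 4, 3)).astype(np.float32)
    y = ReLU().forward(x)
    assert (y >= 0).all()
    s = Sigmoid().forward(x * 10)
    assert ((s >= 0) & (s <= 1)).all()
    assert np.all(np.diff(Sigmoid().forward(np.linspace(-4, 4, 9))) > 0)


def test_adam_reduces_simple_quadratic():
    layer = Conv2D(1, 1, 1)
    layer.params["w"][...] = 5.0
    opt = Adam([layer], lr=0.5)
    for _ in range(100):
        layer.grads = {"w": 2 * layer.params["w"], "b": np.zeros(1, np.float32)}
        opt.step()
    assert abs(layer.params["w"].item()) < 0.5
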