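"""Trainable layers used by the segmentation network.

Each layer owns its parameters (``params`` dict) and accumulates gradients
into ``grads`` during :meth:`backward`.  Tensors are NHWC float32.
"""

from __future__ import annotations

import numpy as np

from . import functional as F


class Layer:
    """Base class: a differentiable op with (possibly empty) parameters."""

    name: str = ""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2D(Layer):
    """Same-padded stride-1 convolution with odd square kernel."""

    def __init__(self, c_in, c_out, kernel_size, name=""):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        self.name = name
        self.params = {
            "w": np.zeros((kernel_size, kernel_size, c_in, c_out), np.float32),
            "b": np.zeros(c_out, np.float32),
        }

    def init_weights(self, rng, sd):
        self.params["w"][...] = rng.normal(0.0, sd, self.params["w"].shape)
        self.params["b"][...] = 0.0

    def forward(self, x, training=False):
        if training:
            y, xs, fs = F.conv2d_forward(
                x, self.params["w"], self.params["b"], return_spectrum=True
            )
            self._cache = (x, xs, fs)
        else:
            y = F.conv2d_forward(x, self.params["w"], self.params["b"])
        return y

    def backward(self, dy):
        x, xs, fs = self._cache
        dx, dw, db = F.conv2d_backward(xs, fs, x, self.params["w"], dy)
        self.grads = {"w": dw, "b": db}
        self._cache = None
        return dx


class ConvTranspose2D(Layer):
    """3x3 stride-2 transpose convolution; doubles the spatial size."""

    def __init__(self, c_in, c_out, name=""):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, 3
        self.name = name
        self.params = {
            "w": np.zeros((3, 3, c_in, c_out), np.float32),
            "b": np.zeros(c_out, np.float32),
        }

    def init_weights(self, rng, sd):
        self.params["w"][...] = rng.normal(0.0, sd, self.params["w"].shape)
        self.params["b"][...] = 0.0

    def forward(self, x, training=False):
        if training:
            self._cache = x
        return F.conv_transpose2d_forward(x, self.params["w"], self.params["b"])

    def backward(self, dy):
        dx, dw, db = F.conv_transpose2d_backward(self._cache, self.params["w"], dy)
        self.grads = {"w": dw, "b": db}
        self._cache = None
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization with learned scale/offset.

    Trainable parameters are gamma/beta only; running mean/variance are
    tracked for inference with momentum ``momentum`` on the running stats.
    """

    def __init__(self, channels, momentum=0.9, eps=1e-5, name=""):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self.params = {
            "gamma": np.ones(channels, np.float32),
            "beta": np.zeros(channels, np.float32),
        }
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        if training:
            self._cache = (xhat.astype(np.float32), inv_sd.astype(np.float32))
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(np.float32)

    def backward(self, dy):
        xhat, inv_sd = self._cache
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dgamma = (dy * xhat).sum(axis=(0, 1, 2))
        dbeta = dy.sum(axis=(0, 1, 2))
        self.grads = {"gamma": dgamma, "beta": dbeta}
        # standard batch-norm backward through the batch statistics
        dx = (self.params["gamma"] * inv_sd / m) * (
            m * dy - dbeta - xhat * dgamma
        )
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training=False):
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; ties share the gradient equally."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        if training:
            self._cache = (xr, y)
        return y

    def backward(self, dy):
        xr, y = self._cache
        mask = (xr == y[:, :, None, :, None, :]).astype(np.float32)
        mask /= mask.sum(axis=(2, 4), keepdims=True)
        dxr = mask * dy[:, :, None, :, None, :]
        n, h2, _, w2, _, c = dxr.shape
        self._cache = None
        return dxr.reshape(n, h2 * 2, w2 * 2, c)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._y = y
        return y

    def backward(self, dy):
        dx = dy * self._y * (1.0 - self._y)
        self._y = None
        return dx
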