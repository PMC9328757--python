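"""Low-level convolution arithmetic on NHWC float32 tensors.

Plain convolutions (odd kernel, stride 1, zero 'same' padding) are evaluated
in the frequency domain: a k x k correlation is a circular convolution on a
zero-extended grid, so forward pass, input gradient and weight gradient all
reduce to rFFT / pointwise product / irFFT at O(HW log HW) per channel pair
instead of O(HW k^2) -- the difference matters for the 7 x 7 kernels used
throughout the network.  Spectra of activations and upstream gradients are
returned to the caller so each tensor is transformed exactly once per
training step.

Conventions: x is (N, H, W, C_in), kernels are (k, k, C_in, C_out),
outputs are (N, H, W, C_out).
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft

__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "conv_transpose2d_forward",
    "conv_transpose2d_backward",
]


def _fft_shape(h: int, w: int, k: int) -> tuple[int, int]:
    return _fft.next_fast_len(h + k - 1), _fft.next_fast_len(w + k - 1)


def conv2d_forward(x, w, b, return_spectrum=False):
    """Same-padded stride-1 correlation of ``x`` with kernel ``w`` plus bias.

    Returns ``y`` or ``(y, x_spectrum, fft_shape)`` when the caller wants to
    reuse the input spectrum for the weight gradient.
    """
    k = w.shape[0]
    if k == 1:  # pointwise conv: a plain matmul is cheapest
        y = x @ w[0, 0] + b
        return (y, None, None) if return_spectrum else y
    if k % 2 == 0:
        raise ValueError("only odd kernel sizes are supported")
    n, h, wd, _ = x.shape
    fh, fw = _fft_shape(h, wd, k)
    xs = _fft.rfft2(x, s=(fh, fw), axes=(1, 2))
    # correlation = convolution with the spatially flipped kernel
    ks = _fft.rfft2(w[::-1, ::-1], s=(fh, fw), axes=(0, 1))
    p = np.einsum("nhwi,hwio->nhwo", xs, ks, optimize=True)
    y = _fft.irfft2(p, s=(fh, fw), axes=(1, 2))
    lo = k // 2  # trailing-only zero padding shifts the 'same' window by k//2
    y = np.ascontiguousarray(y[:, lo : lo + h, lo : lo + wd, :], dtype=x.dtype)
    y += b
    if return_spectrum:
        return y, xs, (fh, fw)
    return y


def conv2d_backward(x_spectrum, fft_shape, x, w, dy):
    """Gradients of a same-padded correlation.

    ``x_spectrum``/``fft_shape`` come from :func:`conv2d_forward`; for 1x1
    kernels they are ``None`` and the matmul path is used.  Returns
    ``(dx, dw, db)``.
    """
    k = w.shape[0]
    db = dy.sum(axis=(0, 1, 2))
    if k == 1:
        n, h, wd, ci = x.shape
        co = dy.shape[3]
        dw = (x.reshape(-1, ci).T @ dy.reshape(-1, co))[None, None]
        dx = dy @ w[0, 0].T
        return dx, dw, db
    n, h, wd, ci = x.shape
    co = dy.shape[3]
    fh, fw = fft_shape
    p = k // 2
    dys = _fft.rfft2(dy, s=(fh, fw), axes=(1, 2))

    # input gradient: same-padded correlation of dy with the spatially
    # flipped, channel-transposed kernel
    kf = _fft.rfft2(w.transpose(0, 1, 3, 2), s=(fh, fw), axes=(0, 1))
    q = np.einsum("nhwo,hwoi->nhwi", dys, kf, optimize=True)
    dx = _fft.irfft2(q, s=(fh, fw), axes=(1, 2))
    lo = k // 2
    dx = np.ascontiguousarray(dx[:, lo : lo + h, lo : lo + wd, :], dtype=x.dtype)

    # weight gradient: dw[a, b, i, o] = sum_{n,r,c} x[n, r+a-p, c+b-p, i] dy[n, r, c, o]
    # i.e. a cross-correlation of x with dy evaluated at the k x k lags,
    # computed as irFFT(conj(dy_hat) * x_hat) read at lags (a - p, b - p).
    g = np.einsum("nhwi,nhwo->hwio", x_spectrum, np.conj(dys), optimize=True)
    corr = _fft.irfft2(g, s=(fh, fw), axes=(0, 1))
    lags = [(a - p) % fh for a in range(k)]
    lagsw = [(b - p) % fw for b in range(k)]
    dw = corr[np.ix_(lags, lagsw)].astype(x.dtype, copy=False)
    return dx, dw, db


def conv_transpose2d_forward(x, w, b):
    """Transpose convolution, kernel 3, stride 2, output = 2x input size.

    The output/input index relation is ``y[2i + a - 1, 2j + b - 1] +=
    x[i, j] @ w[a, b]`` for kernel taps a, b in {0, 1, 2} (out-of-range
    targets dropped), matching the 'same'-padded stride-2 transpose
    convolution used by mainstream frameworks.
    """
    if w.shape[0] != 3 or w.shape[1] != 3:
        raise ValueError("transpose convolution is implemented for 3x3 kernels")
    n, h, wd, ci = x.shape
    co = w.shape[3]
    y = np.zeros((n, 2 * h, 2 * wd, co), dtype=x.dtype)
    for a in range(3):
        rs, ri = _t_slices(a, h)
        for bb in range(3):
            cs, cj = _t_slices(bb, wd)
            y[:, rs, cs, :] += x[:, ri, cj, :] @ w[a, bb]
    y += b
    return y


def _t_slices(a: int, size: int):
    """Output slice and input slice for kernel tap ``a`` along one axis."""
    if a == 0:  # targets 2i - 1, valid for i >= 1
        return slice(1, 2 * size - 2, 2), slice(1, size)
    if a == 1:  # targets 2i
        return slice(0, 2 * size, 2), slice(0, size)
    return slice(1, 2 * size, 2), slice(0, size)  # targets 2i + 1


def conv_transpose2d_backward(x, w, dy):
    """Gradients of :func:`conv_transpose2d_forward`; returns (dx, dw, db)."""
    n, h, wd, ci = x.shape
    co = w.shape[3]
    db = dy.sum(axis=(0, 1, 2))
    dx = np.zeros_like(x)
    dw = np.zeros_like(w)
    for a in range(3):
        rs, ri = _t_slices(a, h)
        for bb in range(3):
            cs, cj = _t_slices(bb, wd)
            dy_ab = dy[:, rs, cs, :]
            dx[:, ri, cj, :] += dy_ab @ w[a, bb].T
            xs = x[:, ri, cj, :]
            dw[a, bb] = xs.reshape(-1, ci).T @ dy_ab.reshape(-1, co)
    return dx, dw, db
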