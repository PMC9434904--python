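"""Minimal convolutional-network layers with hand-derived backprop.

Supports exactly what the pix2pix translator needs: strided convolution,
strided transposed convolution, instance normalization, leaky/plain ReLU,
tanh, sigmoid cross-entropy, and Adam — all on float32 NCHW arrays, all
deterministic for a fixed seed on a single CPU thread.

Convolutions use im2col/col2im so the inner loops are BLAS matmuls.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


def _im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """(N,C,H,W) -> (N, OH*OW, C*k*k) patch matrix."""
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    n, c, oh, ow = win.shape[:4]
    return (np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
            .reshape(n, oh * ow, c * k * k)), oh, ow


def _col2im(cols: np.ndarray, out_hw: tuple, k: int, s: int, p: int,
            oh: int, ow: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`.

    ``cols``: (N, OH*OW, C*k*k); returns (N, C, H, W) with H, W = out_hw.
    """
    n = cols.shape[0]
    c = cols.shape[2] // (k * k)
    h, w = out_hw
    cols = cols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for ki in range(k):
        for kj in range(k):
            out[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += cols[:, :, ki, kj]
    if p:
        out = out[:, :, p:-p, p:-p]
    return out


class Conv2d:
    """k x k convolution, stride s, zero padding p."""

    def __init__(self, in_ch, out_ch, k=4, stride=2, pad=1, rng=None, std=0.02):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Param(rng.normal(0.0, std, (out_ch, in_ch, k, k)))
        self.b = Param(np.zeros(out_ch))
        self.params = [self.w, self.b]
        self._cache = None

    def forward(self, x):
        cols, oh, ow = _im2col(x, self.k, self.s, self.p)
        wmat = self.w.data.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.b.data
        self._cache = (cols, x.shape, oh, ow)
        return np.ascontiguousarray(
            y.reshape(x.shape[0], oh, ow, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, dy):
        cols, x_shape, oh, ow = self._cache
        n = dy.shape[0]
        dy2 = dy.transpose(0, 2, 3, 1).reshape(n, oh * ow, self.out_ch)
        wmat = self.w.data.reshape(self.out_ch, -1)
        self.w.grad += np.einsum("nij,nik->jk", dy2, cols,
                                 optimize=True).reshape(self.w.data.shape)
        self.b.grad += dy2.sum(axis=(0, 1))
        dcols = dy2 @ wmat
        return _col2im(dcols, x_shape[2:], self.k, self.s, self.p, oh, ow)


class ConvTranspose2d:
    """k x k transposed convolution (fractional stride upsampling)."""

    def __init__(self, in_ch, out_ch, k=4, stride=2, pad=1, rng=None, std=0.02):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Param(rng.normal(0.0, std, (in_ch, out_ch, k, k)))
        self.b = Param(np.zeros(out_ch))
        self.params = [self.w, self.b]
        self._cache = None

    def out_size(self, h):
        return (h - 1) * self.s - 2 * self.p + self.k

    def forward(self, x):
        n, _, h, w = x.shape
        x2 = x.transpose(0, 2, 3, 1).reshape(n, h * w, self.in_ch)
        wmat = self.w.data.reshape(self.in_ch, -1)
        colsT = x2 @ wmat  # (N, H*W, out_ch*k*k)
        oh_out, ow_out = self.out_size(h), self.out_size(w)
        y = _col2im(colsT, (oh_out, ow_out), self.k, self.s, self.p, h, w)
        y += self.b.data[None, :, None, None]
        self._cache = (x2, (h, w))
        return y

    def backward(self, dy):
        x2, (h, w) = self._cache
        n = dy.shape[0]
        cols_dy, oh, ow = _im2col(dy, self.k, self.s, self.p)
        # conv geometry guarantees oh == h, ow == w
        wmat = self.w.data.reshape(self.in_ch, -1)
        self.w.grad += np.einsum("nij,nik->jk", x2, cols_dy,
                                 optimize=True).reshape(self.w.data.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx2 = cols_dy @ wmat.T
        return np.ascontiguousarray(
            dx2.reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2))


class InstanceNorm2d:
    """Per-sample per-channel normalization with affine parameters.

    Equivalent to batch normalization at batch size 1 and deterministic at
    inference (statistics come from the instance itself).
    """

    def __init__(self, ch, eps=1e-5):
        self.eps = eps
        self.g = Param(np.ones(ch))
        self.bias = Param(np.zeros(ch))
        self.params = [self.g, self.bias]
        self._cache = None

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.g.data[None, :, None, None] * xhat + self.bias.data[None, :, None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        self.g.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.g.data[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class LeakyReLU:
    def __init__(self, slope=0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh:
    def __init__(self):
        self._y = None

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y * self._y)


def bce_with_logits(z: np.ndarray, target: float):
    """Mean sigmoid cross-entropy against a constant 0/1 target.

    Returns (loss, dloss/dz); numerically stable log1p form.
    """
    loss = float(np.mean(np.maximum(z, 0.0) - z * target + np.log1p(np.exp(-np.abs(z)))))
    dz = (1.0 / (1.0 + np.exp(-z)) - target) / z.size
    return loss, dz.astype(DTYPE)


class Adam:
    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def collect_params(layers) -> list:
    out = []
    for layer in layers:
        out.extend(getattr(layer, "params", []))
    return out


def get_weights(layers) -> list:
    return [p.data.copy() for p in collect_params(layers)]


def set_weights(layers, weights) -> None:
    params = collect_params(layers)
    if len(params) != len(weights):
        raise ValueError("weight list does not match the network")
    for p, w in zip(params, weights):
        if p.data.shape != w.shape:
            raise ValueError(f"shape mismatch {p.data.shape} vs {w.shape}")
        p.data[...] = w
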