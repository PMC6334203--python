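"""Layer primitives with explicit forward caches and backward passes."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


# ---------------------------------------------------------------- conv core

def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> Tuple[np.ndarray, Tuple[int, int]]:
    """(N, C, H, W) -> (N, Ho, Wo, C*k*k) patches."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C, k, k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    n, ho, wo = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, ho, wo, -1), (ho, wo)


def _col2im(dcols: np.ndarray, x_shape: Tuple[int, ...], k: int, stride: int,
            pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter (N, Ho, Wo, C*k*k) back onto (N, C, H, W)."""
    n, c, h, w = x_shape
    ho, wo = dcols.shape[1], dcols.shape[2]
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] \
                += d[:, :, :, :, ki, kj]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d_forward(x, W, b, stride, pad):
    cols, (ho, wo) = _im2col(x, W.shape[-1], stride, pad)
    y = cols @ W.reshape(W.shape[0], -1).T
    if b is not None:
        y = y + b
    return y.transpose(0, 3, 1, 2), cols


def conv2d_backward(dy, x_shape, cols, W, stride, pad):
    k = W.shape[-1]
    dyt = dy.transpose(0, 2, 3, 1)  # (N, Ho, Wo, Co)
    dW = np.tensordot(dyt, cols, axes=([0, 1, 2], [0, 1, 2])).reshape(W.shape)
    db = dyt.sum(axis=(0, 1, 2))
    dcols = dyt @ W.reshape(W.shape[0], -1)
    dx = _col2im(dcols, x_shape, k, stride, pad)
    return dx, dW, db


def conv2d_input_grad(dy, W, stride, pad, x_hw):
    """Gradient of a convolution w.r.t. its input — also the forward map of
    the corresponding transposed convolution."""
    n = dy.shape[0]
    c = W.shape[1]
    dyt = dy.transpose(0, 2, 3, 1)
    dcols = dyt @ W.reshape(W.shape[0], -1)
    return _col2im(dcols, (n, c) + tuple(x_hw), W.shape[-1], stride, pad)


def conv2d_weight_grad(x, dy, k, stride, pad):
    """dW for a conv with input ``x`` and output gradient ``dy``."""
    cols, _ = _im2col(x, k, stride, pad)
    dyt = dy.transpose(0, 2, 3, 1)
    co = dy.shape[1]
    ci = x.shape[1]
    return np.tensordot(dyt, cols, axes=([0, 1, 2], [0, 1, 2])).reshape(co, ci, k, k)


# ------------------------------------------------------------------- layers

class Conv2d:
    """Same-padding-capable 2D convolution."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: Optional[int] = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.k = k
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.standard_normal((c_out, c_in, k, k)) * scale)
        self.b = Param(np.zeros(c_out))

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x):
        y, cols = conv2d_forward(x, self.W.value, self.b.value, self.stride, self.pad)
        return y, (x.shape, cols)

    def backward(self, dy, cache):
        x_shape, cols = cache
        dx, dW, db = conv2d_backward(dy, x_shape, cols, self.W.value,
                                     self.stride, self.pad)
        self.W.grad += dW
        self.b.grad += db
        return dx


class ConvTranspose2d:
    """Transposed convolution (stride-2 upsampling in the decoder).

    With kernel 4, stride 2, pad 1 the output is exactly twice the input
    resolution. Weight layout (c_in, c_out, k, k): the layer is the adjoint
    of a convolution mapping c_out -> c_in.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.pad, self.k = stride, pad, k
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.standard_normal((c_in, c_out, k, k)) * scale)
        self.b = Param(np.zeros(c_out))

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def out_hw(self, h: int, w: int) -> Tuple[int, int]:
        return ((h - 1) * self.stride + self.k - 2 * self.pad,
                (w - 1) * self.stride + self.k - 2 * self.pad)

    def forward(self, x):
        hw = self.out_hw(*x.shape[2:])
        y = conv2d_input_grad(x, self.W.value, self.stride, self.pad, hw)
        y += self.b.value[None, :, None, None]
        return y, x

    def backward(self, dy, cache):
        x = cache
        dx, _ = conv2d_forward(dy, self.W.value, None, self.stride, self.pad)
        self.W.grad += conv2d_weight_grad(dy, x, self.k, self.stride, self.pad)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, train: bool = True):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        return y, (xhat, inv, train)

    def backward(self, dy, cache):
        xhat, inv, train = cache
        g = self.gamma.value[None, :, None, None]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * g
        if not train:
            return dxhat * inv[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = Param(rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in))
        self.b = Param(np.zeros(n_out))

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x):
        return x @ self.W.value.T + self.b.value, x

    def backward(self, dy, cache):
        x = cache
        self.W.grad += dy.T @ x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


def relu(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dy, mask):
    return dy * mask


def max_pool2(x):
    """2x2 max pooling; returns pooled output and an argmax cache."""
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    xf = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = xf.argmax(axis=-1)
    y = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def max_pool2_backward(dy, cache):
    idx, x_shape = cache
    n, c, h, w = x_shape
    dxf = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dxf, idx[..., None], dy[..., None], axis=-1)
    dx = dxf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(n, c, h, w)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class ConvLSTMCell:
    """Convolutional LSTM: gate pre-activations are convolutions of the
    input and hidden state, so the hidden state keeps spatial structure.

    The cell supports a ``None`` input (free-running rollout with zero
    exogenous drive): the input convolution is simply skipped.
    """

    def __init__(self, c_in: int, c_hidden: int, k: int = 5,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.c_in, self.c_hidden, self.k = c_in, c_hidden, k
        pad = (k - 1) // 2
        sx = np.sqrt(1.0 / (c_in * k * k))
        sh = np.sqrt(1.0 / (c_hidden * k * k))
        self.Wx = Param(rng.standard_normal((4 * c_hidden, c_in, k, k)) * sx)
        self.Wh = Param(rng.standard_normal((4 * c_hidden, c_hidden, k, k)) * sh)
        b = np.zeros(4 * c_hidden)
        b[c_hidden:2 * c_hidden] = 1.0  # forget-gate bias
        self.b = Param(b)
        self.pad = pad

    def params(self) -> List[Param]:
        return [self.Wx, self.Wh, self.b]

    def init_state(self, n: int, h: int, w: int):
        z = np.zeros((n, self.c_hidden, h, w))
        return z, z.copy()

    def forward(self, x, hc):
        h_prev, c_prev = hc
        z, cols_h = conv2d_forward(h_prev, self.Wh.value, self.b.value, 1, self.pad)
        cols_x = None
        if x is not None:
            zx, cols_x = conv2d_forward(x, self.Wx.value, None, 1, self.pad)
            z = z + zx
        C = self.c_hidden
        i = _sigmoid(z[:, :C])
        f = _sigmoid(z[:, C:2 * C])
        o = _sigmoid(z[:, 2 * C:3 * C])
        g = np.tanh(z[:, 3 * C:])
        c_new = f * c_prev + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache = (x.shape if x is not None else None, cols_x, h_prev.shape,
                 cols_h, c_prev, i, f, o, g, tc)
        return (h_new, c_new), cache

    def backward(self, dh, dc, cache):
        """Returns (dx, dh_prev, dc_prev); dx is None for a zero-input step."""
        x_shape, cols_x, h_shape, cols_h, c_prev, i, f, o, g, tc = cache
        C = self.c_hidden
        do = dh * tc
        dct = dc + dh * o * (1.0 - tc**2)
        di = dct * g
        dg = dct * i
        df = dct * c_prev
        dc_prev = dct * f
        dz = np.concatenate([
            di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
            dg * (1 - g**2)], axis=1)
        dh_prev, dWh, db = conv2d_backward(dz, h_shape, cols_h, self.Wh.value,
                                           1, self.pad)
        self.Wh.grad += dWh
        self.b.grad += db
        dx = None
        if x_shape is not None:
            dx, dWx, _ = conv2d_backward(dz, x_shape, cols_x, self.Wx.value,
                                         1, self.pad)
            self.Wx.grad += dWx
        return dx, dh_prev, dc_prev


def collect_params(*layers) -> List[Param]:
    out: List[Param] = []
    for layer in layers:
        out.extend(layer.params())
    return out


def get_state(params: List[Param]) -> List[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: List[Param], state: List[np.ndarray]) -> None:
    for p, v in zip(params, state):
        p.value[...] = v
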