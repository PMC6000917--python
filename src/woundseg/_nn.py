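"""Minimal CNN kernel: layers with explicit forward/backward passes.

Everything operates on float32 NCHW arrays.  This is deliberately a small,
fully deterministic numpy implementation — convolutions via strided im2col
views and tensordot, fixed (non-learned) bilinear interpolation, standard
batch normalization, and Adam with decoupled weight decay.  It covers exactly
what the segmentation network needs and nothing else.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU",
    "BilinearUpsample",
    "softmax_cross_entropy",
    "Adam",
]


class Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # whether weight decay applies (convs yes, BN/bias no)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Read-only (N, C, Ho, Wo, k, k) sliding-window view of a padded input."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sn, sc, sh, sw = x.strides
    return np.lib.stride_tricks.as_strided(
        x, (n, c, ho, wo, k, k), (sn, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    ), x.shape


class Conv2d:
    """k x k convolution, 'same' padding, optional stride and bias."""

    def __init__(self, cin: int, cout: int, k: int, stride: int,
                 rng: np.random.Generator, bias: bool = False):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Param(rng.normal(0.0, scale, (cout, cin, k, k)).astype(np.float32))
        self.bias = Param(np.zeros(cout, dtype=np.float32), decay=False) if bias else None
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None

    @property
    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if self.k == 1 and self.stride == 1:
            y = np.tensordot(self.weight.value[:, :, 0, 0], x, axes=([1], [1]))
            y = y.transpose(1, 0, 2, 3)
            self._cache = (x, None)
        else:
            view, padded_shape = _im2col(x, self.k, self.stride, self.pad)
            y = np.tensordot(view, self.weight.value, axes=([1, 4, 5], [1, 2, 3]))
            y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
            self._cache = (x, padded_shape)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, padded_shape = self._cache
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if self.k == 1 and self.stride == 1:
            w = self.weight.value[:, :, 0, 0]
            self.weight.grad[:, :, 0, 0] += np.tensordot(dy, x, axes=([0, 2, 3], [0, 2, 3]))
            dx = np.tensordot(w.T, dy, axes=([1], [1])).transpose(1, 0, 2, 3)
            return np.ascontiguousarray(dx)
        view, _ = _im2col(x, self.k, self.stride, self.pad)
        self.weight.grad += np.tensordot(dy, view, axes=([0, 2, 3], [0, 2, 3]))
        # scatter the gradient back through each kernel offset
        n, _, ho, wo = dy.shape
        dxp = np.zeros(padded_shape, dtype=np.float32)
        s = self.stride
        dcols = np.tensordot(dy, self.weight.value, axes=([1], [0]))  # n,ho,wo,cin,k,k
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[..., ki, kj]
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp


class DepthwiseConv2d:
    """Per-channel 3x3 convolution ('same' padding)."""

    def __init__(self, channels: int, stride: int, rng: np.random.Generator, k: int = 3):
        scale = np.sqrt(2.0 / (k * k))
        self.weight = Param(rng.normal(0.0, scale, (channels, k, k)).astype(np.float32))
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None

    @property
    def params(self):
        return [self.weight]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        view, padded_shape = _im2col(x, self.k, self.stride, self.pad)
        y = np.einsum("nchwij,cij->nchw", view, self.weight.value, optimize=True)
        self._cache = (x, padded_shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, padded_shape = self._cache
        view, _ = _im2col(x, self.k, self.stride, self.pad)
        self.weight.grad += np.einsum("nchwij,nchw->cij", view, dy, optimize=True)
        n, _, ho, wo = dy.shape
        dxp = np.zeros(padded_shape, dtype=np.float32)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += (
                    dy * self.weight.value[None, :, ki, kj, None, None]
                )
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp


class BatchNorm2d:
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32), decay=False)
        self.beta = Param(np.zeros(channels, dtype=np.float32), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        sum_dy = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (g * inv_std[None, :, None, None] / m) * (m * dy - sum_dy - xhat * sum_dy_xhat)
        return dx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[i, lo] += 1.0 - frac
        m[i, hi] += frac
    return m


class BilinearUpsample:
    """Fixed (parameter-free) bilinear upsampling by an integer factor."""

    def __init__(self, factor: int):
        self.factor = factor
        self._mats: dict[tuple[int, int], np.ndarray] = {}

    params: list = []

    def _mat(self, n_in: int) -> np.ndarray:
        key = (n_in, self.factor)
        if key not in self._mats:
            self._mats[key] = _interp_matrix(n_in * self.factor, n_in)
        return self._mats[key]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        mh = self._mat(x.shape[2])
        mw = self._mat(x.shape[3])
        self._shape = x.shape
        y = np.tensordot(x, mh, axes=([2], [1]))  # n,c,w,Ho
        y = np.tensordot(y, mw, axes=([2], [1]))  # n,c,Ho,Wo
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mh = self._mat(self._shape[2])
        mw = self._mat(self._shape[3])
        dx = np.tensordot(dy, mh, axes=([2], [0]))  # n,c,Wo,h
        dx = np.tensordot(dx, mw, axes=([2], [0]))  # n,c,h,w
        return np.ascontiguousarray(dx)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean pixelwise two-class cross entropy.

    Returns ``(loss, dlogits)`` with the gradient already normalized by the
    number of pixels.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n, _, h, w = logits.shape
    idx = np.arange(2)[None, :, None, None] == targets[:, None, :, :]
    eps = 1e-12
    loss = -np.log(probs[idx].clip(eps)).mean()
    dlogits = (probs - idx) / (n * h * w)
    return float(loss), dlogits.astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay and p.decay:
                update = update + self.weight_decay * p.value
            p.value -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
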