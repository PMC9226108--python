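"""Minimal CPU neural-network engine used by the U-Net segmentation model.

Implements exactly the pieces the segmentation network needs — 2D "same"
convolution via im2col, batch normalization, ReLU, 2x2 max pooling, 2x2
stride-2 transposed convolution, sigmoid, soft-Dice loss with analytic
gradient, and Adam — all in numpy with explicit backward passes.  Tensors are
channel-first: (N, C, H, W), float32.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, zero 'same' padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError(f"kernel size must be odd, got {k}")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = Param(w)
        self.b = Param(np.zeros(cout))
        self._cols: Optional[np.ndarray] = None
        self._xshape: Optional[Tuple[int, ...]] = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        n, c, h, w = x.shape
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        if train:
            self._cols, self._xshape = cols, x.shape
        out = cols @ self.w.value.reshape(self.cout, -1).T + self.b.value
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = dout.shape
        k, p = self.k, self.k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.w.grad += (dflat.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += dflat.sum(axis=0)
        dcols = dflat @ self.w.value.reshape(self.cout, -1)
        dcols = dcols.reshape(n, h, w, self.cin, k, k)
        dxp = np.zeros((n, self.cin, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (input H, W must be even)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._inshape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return dx.reshape(n, c, h, w)


class UpConv2d(Layer):
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout, 2, 2))
        self.w = Param(w)
        self.b = Param(np.zeros(cout))

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        n, c, h, w = x.shape
        out = np.einsum("nchw,cfab->nfhawb", x, self.w.value, optimize=True)
        out = out.reshape(n, self.cout, 2 * h, 2 * w)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, H, W = dout.shape
        d = dout.reshape(n, f, H // 2, 2, W // 2, 2)
        self.w.grad += np.einsum("nchw,nfhawb->cfab", self._x, d, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dx = np.einsum("nfhawb,cfab->nchw", d, self.w.value, optimize=True)
        self._x = None
        return dx.astype(np.float32)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def soft_dice(pred: np.ndarray, target: np.ndarray,
              eps: float = 1e-6) -> Tuple[float, np.ndarray]:
    """Soft Dice coefficient over the whole batch and its gradient wrt pred."""
    p = pred.astype(np.float64)
    t = target.astype(np.float64)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    dice = (2.0 * inter + eps) / (denom + eps)
    # d dice / d p = (2 t (denom+eps) - (2 inter + eps)) / (denom+eps)^2
    grad = (2.0 * t * (denom + eps) - (2.0 * inter + eps)) / (denom + eps) ** 2
    return dice, grad.astype(np.float32)


class Adam:
    def __init__(self, params: List[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
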