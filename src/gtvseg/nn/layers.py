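"""Minimal numpy building blocks for a small 2D segmentation CNN.

Every layer is an object with ``forward(x, train)`` and ``backward(dout)``;
trainable arrays live in ``layer.params`` and their gradients (populated by
``backward``) in ``layer.grads``, keyed by the same names.  All arithmetic is
float32 and single-threaded-deterministic: identical inputs and parameters
give bit-identical outputs, which the training/prediction reproducibility
contracts rely on.

Feature maps use the (N, C, H, W) layout throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

DTYPE = np.float32


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Unfold k x k stride-1 patches of x (N,C,H,W) into (N, C*k*k, H*W)."""
    n, c, h, w = x.shape
    if k == 1:
        return x.reshape(n, c, h * w)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of patch gradients)."""
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=DTYPE)
    d = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += d[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Layer:
    """Base: layers without parameters inherit empty params/grads."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 convolution with 'same' zero padding and a bias term.

    kernel_size 3 (pad 1) for the body of the network, 1 (pad 0) for the
    attention-gate projections and the output head.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        self.pad = kernel_size // 2
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel_size * kernel_size
        # He-uniform initialization; bound sqrt(6/fan_in).
        bound = np.sqrt(6.0 / fan_in)
        self.params["W"] = rng.uniform(-bound, bound, size=(c_out, fan_in)).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self._cache = None

    @property
    def n_parameters(self) -> int:
        return self.params["W"].size + self.params["b"].size

    def forward(self, x, train=False):
        x = x.astype(DTYPE, copy=False)
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        cols = _im2col(x, self.k, self.pad)
        out = np.matmul(self.params["W"], cols) + self.params["b"][:, None]
        self._cache = (cols, x.shape) if train else None
        return out.reshape(n, self.c_out, h, w)

    def backward(self, dout):
        cols, xshape = self._cache
        n, c, h, w = xshape
        dflat = dout.reshape(n, self.c_out, h * w).astype(DTYPE, copy=False)
        # dW = sum_n dout_n @ cols_n^T, as one batched BLAS call
        self.grads["W"] = np.matmul(dflat, cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.params["W"].T, dflat)
        return _col2im(dcols, xshape, self.k, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learnable scale/shift.

    Training uses batch statistics and updates exponential running moments;
    inference uses the frozen running moments so prediction is deterministic.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.params["gamma"] = np.ones(c, dtype=DTYPE)
        self.params["beta"] = np.zeros(c, dtype=DTYPE)
        # running statistics are state, not trainable parameters
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        # frozen_stats: normalize with the stored running moments even while
        # training (the fine-tuning guard against catastrophic forgetting)
        self.frozen_stats = False
        self._cache = None

    @property
    def n_parameters(self) -> int:
        return 2 * self.c

    def forward(self, x, train=False):
        x = x.astype(DTYPE, copy=False)
        batch_stats = train and not self.frozen_stats
        if batch_stats:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std, batch_stats)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dout):
        xhat, inv_std, batch_stats = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = np.einsum("nchw,nchw->c", dout, xhat, optimize=True)
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][None, :, None, None]
        if not batch_stats:
            # frozen moments are constants w.r.t. the input
            return (dxhat * inv_std[None, :, None, None]).astype(DTYPE, copy=False)
        mean_d = dxhat.mean(axis=(0, 2, 3))
        mean_dx = np.einsum("nchw,nchw->c", dxhat, xhat, optimize=True) / m
        dx = inv_std[None, :, None, None] * (
            dxhat
            - mean_d[None, :, None, None]
            - xhat * mean_dx[None, :, None, None]
        )
        return dx.astype(DTYPE, copy=False)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        super().__init__()
        self.alpha = alpha
        self._mask = None

    def forward(self, x, train=False):
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Sigmoid(Layer):
    def __init__(self):
        super().__init__()
        self._out = None

    def forward(self, x, train=False):
        # numerically stable logistic (no overflow for large |x|)
        out = expit(x)
        if train:
            self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2. Ties route to the first maximal position."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, xshape = self._cache
        n, c, h, w = xshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], dout[..., None].astype(DTYPE), axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpsampleNearest2x(Layer):
    """Nearest-neighbour 2x upsampling; adjoint is 2x2 block summation."""

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam optimizer over a flat {name: array} parameter dictionary."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for name, p in params.items():
            g = grads[name]
            if name not in self.m:
                self.m[name] = np.zeros_like(p)
                self.v[name] = np.zeros_like(p)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / bias1
            vhat = self.v[name] / bias2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
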