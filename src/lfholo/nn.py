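"""Minimal fully-convolutional network engine on numpy.

Implements exactly the layer set the unwrapping network needs — stride-1
same-padded 2D convolution, per-channel batch normalization and ReLU — with
manual reverse-mode gradients and an Adam optimizer.  Arrays are NCHW.
Convolutions are evaluated as matrix products over sliding-window views,
which is the fastest pure-numpy route at the feature counts used here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "BatchNorm2D", "ReLU", "Sequential", "Adam", "mse_loss"]


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding k×k windows of a padded NCHW array → (N, C, H, W, k, k)."""
    return np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))


class Conv2D:
    """Stride-1 convolution with zero same-padding and bias."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator) -> None:
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.k = k
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU stacks
        self.W = rng.normal(0.0, scale, (c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = xp if training else None
        win = _windows(xp, self.k)
        return np.einsum("nchwij,fcij->nfhw", win, self.W, optimize=True) \
            + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.k // 2
        win = _windows(self._xp, self.k)
        self.gW += np.einsum("nchwij,nfhw->fcij", win, dout, optimize=True)
        self.gb += dout.sum(axis=(0, 2, 3))
        # dx: full correlation of dout with the kernel, i.e. convolution with
        # the spatially flipped kernel transposed over channels
        dpad = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        wflip = self.W[:, :, ::-1, ::-1]
        dwin = _windows(dpad, self.k)
        dx = np.einsum("nfhwij,fcij->nchw", dwin, wflip, optimize=True)
        self._xp = None
        return dx


class BatchNorm2D:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[2] * x.shape[3]
        return xhat * self.gamma[None, :, None, None] + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._xhat, self._inv, self._m
        self.ggamma += (dout * xhat).sum(axis=(0, 2, 3))
        self.gbeta += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        # standard batch-norm backward over the (N, H, W) reduction axes
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._xhat = None
        return dx


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        mask = x > 0
        if training:
            self._mask = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class Sequential:
    def __init__(self, layers: list) -> None:
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for name in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, name):
                    state[f"{i}.{name}"] = getattr(layer, name)
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                key = f"{i}.{name}"
                if hasattr(layer, name):
                    getattr(layer, name)[...] = state[key]


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.params()]
        self.v = [np.zeros_like(p) for p, _ in model.params()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.model.params(), self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean-squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size
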