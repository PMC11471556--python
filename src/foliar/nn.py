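"""Minimal numpy layer engine: forward/backward primitives and optimizers.

Implements exactly the layer kinds the architecture graphs use (convolution
with groups, batch normalization, ReLU, max/global-average pooling, dense,
single-head self-attention over a pooled vector) plus the few extras the
augmentation autoencoder needs (nearest-neighbor upsampling, sigmoid).

Convolutions use same-padding ``p = (k - 1) // 2`` and the output-size rule
``floor((H + 2p - k) / s) + 1``; they are evaluated as grouped matrix products
over sliding windows.  Everything is float64 and deterministic given the
``numpy.random.Generator`` used at construction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ReLU",
    "Sigmoid",
    "BatchNorm2D",
    "MaxPool2D",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "VecSelfAttention",
    "Upsample2D",
    "softmax",
    "softmax_cross_entropy",
    "SGDMomentum",
    "Adam",
]


class Layer:
    """Single-input layer; subclasses fill ``params``/``grads`` name-keyed dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _conv_geometry(h: int, w: int, k: int, s: int) -> tuple[int, int, int]:
    p = (k - 1) // 2
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    return p, ho, wo


class Conv2D(Layer):
    """2-D convolution, NCHW, same-padding, optional channel groups."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int,
        stride: int = 1,
        groups: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channels must divide groups")
        self.in_ch, self.out_ch, self.k, self.stride, self.groups = (
            in_ch,
            out_ch,
            k,
            stride,
            groups,
        )
        rng = rng or np.random.default_rng(0)
        fan_in = (in_ch // groups) * k * k
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch // groups, k, k)
        )
        self.params["b"] = np.zeros(out_ch)

    def _columns(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
        n, c, h, w = x.shape
        k, s, g = self.k, self.stride, self.groups
        p, ho, wo = _conv_geometry(h, w, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (N, g, Ho*Wo, (C/g)*k*k)
        cols = (
            win.reshape(n, g, c // g, ho, wo, k, k)
            .transpose(0, 1, 3, 4, 2, 5, 6)
            .reshape(n, g, ho * wo, (c // g) * k * k)
        )
        return cols, (p, ho, wo)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n = x.shape[0]
        g, og = self.groups, self.out_ch // self.groups
        cols, (p, ho, wo) = self._columns(x)
        wm = self.params["W"].reshape(g, og, -1).transpose(0, 2, 1)  # (g, CgKK, Og)
        y = cols @ wm  # (N, g, HW, Og)
        y = y.transpose(0, 1, 3, 2).reshape(n, self.out_ch, ho, wo)
        y += self.params["b"][None, :, None, None]
        if train:
            self._cache = (cols, x.shape, p, ho, wo)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, p, ho, wo = self._cache
        n, c, h, w = x_shape
        k, s, g = self.k, self.stride, self.groups
        og, cg = self.out_ch // g, c // g
        dym = dy.reshape(n, g, og, ho * wo).transpose(0, 1, 3, 2)  # (N,g,HW,Og)
        dwm = np.einsum("ngpi,ngpo->gio", cols, dym)  # (g, CgKK, Og)
        self.grads["W"] = dwm.transpose(0, 2, 1).reshape(self.params["W"].shape)
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        wm = self.params["W"].reshape(g, og, -1).transpose(0, 2, 1)
        dcols = dym @ wm.transpose(0, 2, 1)  # (N,g,HW,CgKK)
        dwin = (
            dcols.reshape(n, g, ho, wo, cg, k, k)
            .transpose(0, 1, 4, 2, 3, 5, 6)
            .reshape(n, c, ho, wo, k, k)
        )
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + (ho - 1) * s + 1 : s, j : j + (wo - 1) * s + 1 : s] += dwin[
                    :, :, :, :, i, j
                ]
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._cache = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, self._cache = self._cache, None
        return dy * mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if train:
            self._cache = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y, self._cache = self._cache, None
        return dy * y * (1.0 - y)


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        y = self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        self._cache = None
        n_eff = shape[0] * shape[2] * shape[3]
        axes = (0, 2, 3)
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / n_eff
        ) * inv[None, :, None, None]
        return dx


class MaxPool2D(Layer):
    def __init__(self, k: int, stride: int) -> None:
        super().__init__()
        self.k, self.stride = k, stride

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        p, ho, wo = _conv_geometry(h, w, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape, p, ho, wo)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, x_shape, p, ho, wo = self._cache
        self._cache = None
        n, c, h, w = x_shape
        k, s = self.k, self.stride
        dflat = np.zeros((n, c, ho, wo, k * k))
        np.put_along_axis(dflat, arg[..., None], dy[..., None], axis=-1)
        dwin = dflat.reshape(n, c, ho, wo, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + (ho - 1) * s + 1 : s, j : j + (wo - 1) * s + 1 : s] += dwin[
                    :, :, :, :, i, j
                ]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C, 1, 1)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x.shape
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape, self._cache = self._cache, None
        n, c, h, w = shape
        return np.broadcast_to(dy / (h * w), shape).copy()


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape, self._cache = self._cache, None
        return dy.reshape(shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_dim), (out_dim, in_dim))
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._cache = self._cache, None
        self.grads["W"] = dy.T @ x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"]


class VecSelfAttention(Layer):
    """Single-head scaled dot-product self-attention over a pooled vector.

    The pooled representation is a single token, so the attention weight is
    identically 1 and the layer output equals the value projection; the
    query/key projections are genuine learnables of the layer (they set its
    parameter count) but receive no gradient through the degenerate softmax.
    ``shared_qk`` uses one projection matrix for both query and key;
    ``qk_dim`` sets the key-channel width.
    """

    def __init__(
        self,
        dim: int,
        qk_dim: int | None = None,
        shared_qk: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.qk_dim = dim if qk_dim is None else qk_dim
        self.shared_qk = shared_qk
        std = np.sqrt(1.0 / dim)
        if shared_qk:
            self.params["Wqk"] = rng.normal(0.0, std, (self.qk_dim, dim))
            self.params["bqk"] = np.zeros(self.qk_dim)
        else:
            self.params["Wq"] = rng.normal(0.0, std, (self.qk_dim, dim))
            self.params["bq"] = np.zeros(self.qk_dim)
            self.params["Wk"] = rng.normal(0.0, std, (self.qk_dim, dim))
            self.params["bk"] = np.zeros(self.qk_dim)
        self.params["Wv"] = rng.normal(0.0, std, (dim, dim))
        self.params["bv"] = np.zeros(dim)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.params["Wv"].T + self.params["bv"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._cache = self._cache, None
        self.grads["Wv"] = dy.T @ x
        self.grads["bv"] = dy.sum(axis=0)
        for name in ("Wqk", "bqk", "Wq", "bq", "Wk", "bk"):
            if name in self.params:
                self.grads[name] = np.zeros_like(self.params[name])
        return dy @ self.params["Wv"]


class Upsample2D(Layer):
    """Nearest-neighbor spatial upsampling by an integer factor."""

    def __init__(self, factor: int = 2) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.factor
        if train:
            self._cache = x.shape
        return x.repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape, self._cache = self._cache, None
        n, c, h, w = shape
        f = self.factor
        return dy.reshape(n, c, h, f, w, f).sum(axis=(3, 5))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.log(np.maximum(probs[np.arange(n), labels], 1e-300)).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class SGDMomentum:
    """Classical momentum: ``v <- mu v - lr g``; ``p <- p + v``."""

    def __init__(self, layers, lr: float, momentum: float = 0.0) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.momentum = lr, momentum
        self.velocity = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        for layer, vel in zip(self.layers, self.velocity):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                vel[name] = self.momentum * vel[name] - self.lr * g
                p += vel[name]


class Adam:
    def __init__(
        self,
        layers,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        for layer, m, v in zip(self.layers, self.m, self.v):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                m[name] = self.b1 * m[name] + (1 - self.b1) * g
                v[name] = self.b2 * v[name] + (1 - self.b2) * g * g
                mhat = m[name] / (1 - self.b1**self.t)
                vhat = v[name] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
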