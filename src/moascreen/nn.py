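"""Minimal deterministic neural-network core (numpy, CPU).

Provides exactly the layers the pipeline's two classifiers need: strided
convolutions (im2col + GEMM), dense layers, ReLU, 1-D batch normalization,
global average pooling, and an Adam optimizer with softmax cross-entropy.
All computation is plain numpy, so training is bit-reproducible for a fixed
seed on a given build — the property the end-to-end determinism contract
relies on.

This is intentionally a small engine, not a framework: no autograd graph,
each layer implements ``forward``/``backward`` explicitly, and parameters
live on the layer objects as ``{"W": ..., "b": ...}`` dicts mirrored by
gradient dicts.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params = {"W": scale * rng.standard_normal((d_in, d_out)),
                       "b": np.zeros(d_out)}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"W": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv2d(Layer):
    """3x3 (by default) strided convolution with symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.params = {"W": scale * rng.standard_normal((fan_in, c_out)),
                       "b": np.zeros(c_out)}

    def _cols(self, xp: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,Hf,Wf,k,k
        win = win[:, :, ::s, ::s]
        # -> N,Ho,Wo,C,k,k
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))

    def forward(self, x, train):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp_shape = xp.shape
        cols = self._cols(xp)
        n, ho, wo = cols.shape[:3]
        self._cols_flat = cols.reshape(n * ho * wo, -1)
        y = self._cols_flat @ self.params["W"] + self.params["b"]
        self._out_hw = (ho, wo)
        return y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, _, ho, wo = dy.shape
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.grads = {"W": self._cols_flat.T @ dy_flat,
                      "b": dy_flat.sum(axis=0)}
        dcols = (dy_flat @ self.params["W"].T).reshape(
            n, ho, wo, self.c_in, self.kernel, self.kernel)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # N,C,k,k,Ho,Wo
        dxp = np.zeros(self._xp_shape)
        s = self.stride
        for i in range(self.kernel):
            for j in range(self.kernel):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, i, j]
        p = self.pad
        return dxp[:, :, p:-p or None, p:-p or None]


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               self._shape).copy()


class BatchNorm1d(Layer):
    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean \
                + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var \
                + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        n = dy.shape[0]
        xhat, std = self._xhat, self._std
        self.grads = {"gamma": (dy * xhat).sum(axis=0),
                      "beta": dy.sum(axis=0)}
        dxhat = dy * self.params["gamma"]
        return (dxhat - dxhat.mean(axis=0)
                - xhat * (dxhat * xhat).mean(axis=0)) / std


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield li, name

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for li, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                state[f"{li}.{name}"] = value.copy()
            if isinstance(layer, BatchNorm1d):
                state[f"{li}.running_mean"] = layer.running_mean.copy()
                state[f"{li}.running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{li}.{name}"].copy()
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = state[f"{li}.running_mean"].copy()
                layer.running_var = state[f"{li}.running_var"].copy()


class Adam:
    def __init__(self, net: Sequential, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.net, self.lr, self.betas, self.eps = net, lr, betas, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for li, name in self.net.parameters():
            layer = self.net.layers[li]
            g = layer.grads[name]
            key = (li, name)
            self.m[key] = b1 * self.m.get(key, 0.0) + (1 - b1) * g
            self.v[key] = b2 * self.v.get(key, 0.0) + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n
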