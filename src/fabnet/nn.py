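"""Minimal NumPy neural-network engine used to compile architecture specs.

Implements exactly the primitives the feature-agglomeration network needs —
stride-1 "same" convolutions, batch normalization, 2x2 average pooling,
global average pooling, a dense layer, and softmax cross-entropy — each with
an explicit backward pass, plus the common first-order optimizers. Data
layout is NCHW throughout. All parameter initialization is driven by a
caller-supplied ``numpy.random.Generator`` so model construction is
deterministic under a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "AvgPool2x2",
    "GlobalAvgPool",
    "Dense",
    "relu",
    "relu_backward",
    "softmax",
    "softmax_cross_entropy",
    "make_optimizer",
]


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    # uniform fan-in init: U(-sqrt(6/fan_in), +sqrt(6/fan_in))
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float64)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dout: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns ``(loss, probs, dlogits)`` with ``dlogits`` already averaged over
    the batch.
    """
    n = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, probs, dlogits


class Layer:
    """Base class: parameters live in ``params``, gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2D(Layer):
    """Stride-1 convolution with zero padding preserving spatial size.

    Weight shape ``(k*k*c_in, c_out)`` (im2col layout); bias ``(c_out,)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = kernel * kernel * c_in
        self.params["w"] = _uniform_fan_in(rng, fan_in, (fan_in, c_out))
        self.params["b"] = np.zeros(c_out)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros_like(self.params["b"])
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (n, c, h, w, k, k) -> rows of length c*k*k
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n * h * w, c * k * k)
        out = cols @ self.params["w"] + self.params["b"]
        if training:
            self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        k, p = self.kernel, self.kernel // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["w"] += cols.T @ dflat
        self.grads["b"] += dflat.sum(axis=0)
        dcols = (dflat @ self.params["w"].T).reshape(n, h, w, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2D(Layer):
    """Per-channel batch normalization with learned scale and shift."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.grads["gamma"] = np.zeros(channels)
        self.grads["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        m = mean[None, :, None, None]
        v = var[None, :, None, None]
        xhat = (x - m) / np.sqrt(v + self.eps)
        if training:
            self._cache = (xhat, var)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, var = self._cache
        n, c, h, w = dout.shape
        m = n * h * w
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        inv_std = 1.0 / np.sqrt(var + self.eps)[None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv_std / m * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class AvgPool2x2(Layer):
    """2x2 average pooling with stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by 2")
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


class GlobalAvgPool(Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["w"] = _uniform_fan_in(rng, d_in, (d_in, d_out))
        self.params["b"] = np.zeros(d_out)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros_like(self.params["b"])
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._cache = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["w"] += x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["w"].T


# ---------------------------------------------------------------------------
# optimizers


class _Optimizer:
    def __init__(self, slots, lr: float):
        # slots: list of (params_dict, grads_dict, key)
        self.slots = slots
        self.lr = lr
        self.t = 0

    def zero_grad(self):
        for params, grads, key in self.slots:
            grads[key][...] = 0.0

    def step(self):
        raise NotImplementedError


class SGD(_Optimizer):
    def step(self):
        for params, grads, key in self.slots:
            params[key] -= self.lr * grads[key]


class Adam(_Optimizer):
    def __init__(self, slots, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(slots, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p[k]) for p, _, k in slots]
        self.v = [np.zeros_like(p[k]) for p, _, k in slots]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (params, grads, key) in enumerate(self.slots):
            g = grads[key]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Adam):
    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (params, grads, key) in enumerate(self.slots):
            g = grads[key]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = np.maximum(b2 * self.v[i], np.abs(g))
            params[key] -= self.lr / (1 - b1**self.t) * self.m[i] / (self.v[i] + self.eps)


class Nadam(Adam):
    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (params, grads, key) in enumerate(self.slots):
            g = grads[key]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = (b1 * self.m[i] + (1 - b1) * g) / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSProp(_Optimizer):
    def __init__(self, slots, lr, rho=0.9, eps=1e-8):
        super().__init__(slots, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p[k]) for p, _, k in slots]

    def step(self):
        for i, (params, grads, key) in enumerate(self.slots):
            g = grads[key]
            self.v[i] = self.rho * self.v[i] + (1 - self.rho) * g * g
            params[key] -= self.lr * g / (np.sqrt(self.v[i]) + self.eps)


class Adadelta(_Optimizer):
    def __init__(self, slots, lr=1.0, rho=0.95, eps=1e-6):
        super().__init__(slots, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p[k]) for p, _, k in slots]
        self.u = [np.zeros_like(p[k]) for p, _, k in slots]

    def step(self):
        for i, (params, grads, key) in enumerate(self.slots):
            g = grads[key]
            self.v[i] = self.rho * self.v[i] + (1 - self.rho) * g * g
            dx = -np.sqrt(self.u[i] + self.eps) / np.sqrt(self.v[i] + self.eps) * g
            self.u[i] = self.rho * self.u[i] + (1 - self.rho) * dx * dx
            params[key] += self.lr * dx


_OPTIMIZERS = {
    "adam": Adam,
    "sgd": SGD,
    "rmsprop": RMSProp,
    "adadelta": Adadelta,
    "adamax": Adamax,
    "nadam": Nadam,
}


def make_optimizer(name: str, layers, lr: float) -> _Optimizer:
    """Build an optimizer over every trainable slot of ``layers``."""
    if name not in _OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}")
    slots = [
        (layer.params, layer.grads, key)
        for layer in layers
        for key in layer.params
    ]
    return _OPTIMIZERS[name](slots, lr)
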