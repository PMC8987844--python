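"""Minimal NumPy convolutional network for small RGB tiles.

Implements exactly the pieces the tile classifier needs: same-padding 3x3
convolutions with ReLU, 2x2 max-pooling, dense layers, inverted dropout, a
single sigmoid output trained with binary cross-entropy, and the Adam
optimizer.  Convolutions are evaluated as matrix products over an im2col
expansion, which is fast enough for 30-px tiles on one CPU.  All
randomness (weight init, dropout masks) flows from explicit generators, so
training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

__all__ = ["Network", "Adam", "sigmoid", "bce_loss"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy from logits (numerically stable)."""
    z = logits.ravel()
    return float(np.mean(np.logaddexp(0.0, z) - y.ravel() * z))


def _glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int, rng) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W,k*k*C) patches under zero ('same') padding."""
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = np.empty((n, h, w, k, k, c), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i : i + h, j : j + w, :]
    return cols.reshape(n, h, w, k * k * c)


def _col2im(dcols: np.ndarray, shape: tuple[int, ...], k: int) -> np.ndarray:
    """Adjoint of `_im2col`: scatter-add patch gradients back to pixels."""
    n, h, w, c = shape
    p = k // 2
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dcols.dtype)
    d6 = dcols.reshape(n, h, w, k, k, c)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + w, :] += d6[:, :, :, i, j, :]
    return dxp[:, p : p + h, p : p + w, :]


class Conv2D:
    """3x3 (configurable) same-padding convolution with ReLU."""

    def __init__(self, filters: int, kernel: int = 3):
        self.filters = filters
        self.kernel = kernel
        self.w: np.ndarray | None = None
        self.b: np.ndarray | None = None

    def build(self, input_shape, rng):
        h, w, c = input_shape
        k = self.kernel
        fan_in, fan_out = k * k * c, k * k * self.filters
        self.w = _glorot_uniform((k * k * c, self.filters), fan_in, fan_out, rng)
        self.b = np.zeros(self.filters, dtype=np.float32)
        return (h, w, self.filters)

    def forward(self, x, train, rng):
        self._in_shape = x.shape
        cols = _im2col(x, self.kernel)
        z = cols @ self.w + self.b
        self._cols = cols if train else None
        self._relu_mask = z > 0 if train else None
        return np.maximum(z, 0.0)

    def backward(self, dy):
        dz = dy * self._relu_mask
        flat_cols = self._cols.reshape(-1, self.w.shape[0])
        flat_dz = dz.reshape(-1, self.filters)
        self.dw = flat_cols.T @ flat_dz
        self.db = flat_dz.sum(axis=0)
        dcols = dz @ self.w.T
        return _col2im(dcols, self._in_shape, self.kernel)

    @property
    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]

    def descriptor(self):
        return {"type": "conv", "filters": self.filters, "kernel": self.kernel,
                "padding": "same", "activation": "relu"}


class MaxPool2D:
    """2x2 max pooling, stride 2, trailing row/column dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def build(self, input_shape, rng):
        h, w, c = input_shape
        return (h // self.size, w // self.size, c)

    def forward(self, x, train, rng):
        s = self.size
        n, h, w, c = x.shape
        h2, w2 = h // s, w // s
        self._in_shape = x.shape
        xc = x[:, : h2 * s, : w2 * s, :]
        patches = xc.reshape(n, h2, s, w2, s, c).transpose(0, 1, 3, 2, 4, 5).reshape(
            n, h2, w2, s * s, c
        )
        self._argmax = patches.argmax(axis=3) if train else None
        return patches.max(axis=3)

    def backward(self, dy):
        s = self.size
        n, h, w, c = self._in_shape
        h2, w2 = h // s, w // s
        dpatch = np.zeros((n, h2, w2, s * s, c), dtype=dy.dtype)
        idx = np.indices((n, h2, w2, c))
        dpatch[idx[0], idx[1], idx[2], self._argmax, idx[3]] = dy
        dx = np.zeros((n, h, w, c), dtype=dy.dtype)
        dx[:, : h2 * s, : w2 * s, :] = (
            dpatch.reshape(n, h2, w2, s, s, c).transpose(0, 1, 3, 2, 4, 5).reshape(
                n, h2 * s, w2 * s, c
            )
        )
        return dx

    @property
    def params(self):
        return []

    def grads(self):
        return []

    def descriptor(self):
        return {"type": "maxpool", "size": self.size}


class Flatten:
    def build(self, input_shape, rng):
        self._shape = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, train, rng):
        self._n = x.shape[0]
        return x.reshape(self._n, -1)

    def backward(self, dy):
        return dy.reshape((self._n,) + self._shape)

    @property
    def params(self):
        return []

    def grads(self):
        return []

    def descriptor(self):
        return {"type": "flatten"}


class Dense:
    def __init__(self, units: int, activation: str = "relu"):
        if activation not in ("relu", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.units = units
        self.activation = activation
        self.w = None
        self.b = None

    def build(self, input_shape, rng):
        (d,) = input_shape
        self.w = _glorot_uniform((d, self.units), d, self.units, rng)
        self.b = np.zeros(self.units, dtype=np.float32)
        return (self.units,)

    def forward(self, x, train, rng):
        self._x = x if train else None
        z = x @ self.w + self.b
        if self.activation == "relu":
            self._relu_mask = z > 0 if train else None
            return np.maximum(z, 0.0)
        return z

    def backward(self, dy):
        dz = dy * self._relu_mask if self.activation == "relu" else dy
        self.dw = self._x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.w.T

    @property
    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]

    def descriptor(self):
        return {"type": "dense", "units": self.units, "activation": self.activation}


class Dropout:
    """Inverted dropout: active only during training passes."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def build(self, input_shape, rng):
        return input_shape

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    @property
    def params(self):
        return []

    def grads(self):
        return []

    def descriptor(self):
        return {"type": "dropout", "rate": self.rate}


_LAYER_TYPES = {"conv": Conv2D, "maxpool": MaxPool2D, "flatten": Flatten,
                "dense": Dense, "dropout": Dropout}


def _layer_from_descriptor(d: dict):
    kind = d["type"]
    if kind == "conv":
        return Conv2D(d["filters"], d.get("kernel", 3))
    if kind == "maxpool":
        return MaxPool2D(d.get("size", 2))
    if kind == "flatten":
        return Flatten()
    if kind == "dense":
        return Dense(d["units"], d.get("activation", "relu"))
    if kind == "dropout":
        return Dropout(d["rate"])
    raise ValueError(f"unknown layer type {kind!r}")


class Network:
    """A feed-forward stack ending in one logit; sigmoid applied on read-out."""

    def __init__(self, layers: Sequence, input_shape: tuple[int, int, int], seed: int = 0):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.build(shape, rng)
        if shape != (1,):
            raise ValueError(f"network must end in a single output unit, got {shape}")

    @classmethod
    def from_descriptor(cls, descriptor: Sequence[dict], input_shape, seed: int = 0) -> "Network":
        return cls([_layer_from_descriptor(d) for d in descriptor], input_shape, seed=seed)

    def descriptor(self) -> list[dict]:
        return [layer.descriptor() for layer in self.layers]

    def forward_logits(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            probs.append(sigmoid(self.forward_logits(x[i : i + batch_size])).ravel())
        return np.concatenate(probs) if probs else np.empty(0)

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for _, p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params:
                out[f"layer{i}_{name}"] = p
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, p in layer.params:
                p[...] = weights[f"layer{i}_{name}"]

    # persistence: weights as .npz beside a JSON descriptor
    def save(self, weights_path, descriptor_path) -> None:
        np.savez(weights_path, **self.get_weights())
        with open(descriptor_path, "w") as fh:
            json.dump({"input_shape": list(self.input_shape), "layers": self.descriptor()}, fh, indent=2)

    @classmethod
    def load(cls, weights_path, descriptor_path) -> "Network":
        with open(descriptor_path) as fh:
            meta = json.load(fh)
        net = cls.from_descriptor(meta["layers"], tuple(meta["input_shape"]), seed=0)
        with np.load(weights_path) as data:
            net.set_weights({k: data[k] for k in data.files})
        return net


class Adam:
    """Adam with the conventional defaults (b1=0.9, b2=0.999, eps=1e-7)."""

    def __init__(self, params: Sequence[np.ndarray], learning_rate: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr = learning_rate
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2 ** self.t) / (1.0 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
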