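"""Minimal neural-network engine used by the prediction sub-models.

Implements exactly the pieces the classifier needs — dense, 1D convolution,
embedding, ReLU, dropout, global max pooling, a two-branch concatenation
container, the Adam optimizer, and multi-label sigmoid binary cross-entropy
— on plain numpy arrays, with explicit backward passes. Everything is seeded
and single-threaded-deterministic: a fixed seed, fixed data, and a fixed
architecture reproduce the training trajectory bit for bit.

Shapes: vector inputs are ``(n, d)``; token inputs are integer ``(n, L)``
and become ``(n, L, channels)`` after the embedding layer; convolutions are
"valid" (no padding) along the length axis.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class Layer:
    """Base layer: stateless unless it declares parameters."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[dict]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization (ReLU-friendly)
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        return [{"value": self.W, "grad": self.dW}, {"value": self.b, "grad": self.db}]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Embedding(Layer):
    """Token ids ``(n, L)`` -> learned vectors ``(n, L, width)``."""

    def __init__(self, n_tokens: int, width: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, 0.1, size=(n_tokens, width))
        self.dW = np.zeros_like(self.W)

    def forward(self, x, train):
        self._tokens = x
        return self.W[x]

    def backward(self, grad):
        self.dW[...] = 0.0
        np.add.at(self.dW, self._tokens, grad)
        return np.zeros_like(self._tokens, dtype=float)  # ids are not trainable

    def parameters(self):
        return [{"value": self.W, "grad": self.dW}]


class Conv1D(Layer):
    """Valid 1D convolution: ``(n, L, c_in)`` -> ``(n, L-k+1, c_out)``."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.k = kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / (kernel * c_in)), size=(kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        n, L, _ = x.shape
        if L < self.k:
            raise ValueError(f"input length {L} shorter than kernel {self.k}")
        self._x = x
        L_out = L - self.k + 1
        out = np.broadcast_to(self.b, (n, L_out, self.b.shape[0])).copy()
        for t in range(self.k):
            out += x[:, t : t + L_out, :] @ self.W[t]
        return out

    def backward(self, grad):
        x = self._x
        L_out = grad.shape[1]
        self.db[...] = grad.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        for t in range(self.k):
            self.dW[t] = np.einsum("nlc,nlo->co", x[:, t : t + L_out, :], grad)
            dx[:, t : t + L_out, :] += grad @ self.W[t].T
        return dx

    def parameters(self):
        return [{"value": self.W, "grad": self.dW}, {"value": self.b, "grad": self.db}]


class GlobalMaxPool(Layer):
    """Max over the length axis: ``(n, L, c)`` -> ``(n, c)``."""

    def forward(self, x, train):
        self._x_shape = x.shape
        self._arg = x.argmax(axis=1)
        return x.max(axis=1)

    def backward(self, grad):
        n, L, c = self._x_shape
        dx = np.zeros(self._x_shape)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        dx[ni, self._arg, ci] = grad
        return dx


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class BranchConcat(Layer):
    """Run one branch per input array and concatenate outputs on axis 1."""

    def __init__(self, branches: Sequence[Layer]):
        self.branches = list(branches)

    def forward(self, xs, train):
        self._outs = [br.forward(x, train) for br, x in zip(self.branches, xs)]
        self._widths = [o.shape[1] for o in self._outs]
        return np.concatenate(self._outs, axis=1)

    def backward(self, grad):
        splits = np.cumsum(self._widths)[:-1]
        grads = np.split(grad, splits, axis=1)
        return tuple(br.backward(g) for br, g in zip(self.branches, grads))

    def parameters(self):
        return [p for br in self.branches for p in br.parameters()]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-class binary cross-entropy and its gradient w.r.t. logits."""
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad


class Adam:
    def __init__(self, params: list[dict], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_weights(net: Layer) -> list[np.ndarray]:
    return [p["value"].copy() for p in net.parameters()]


def set_weights(net: Layer, weights: list[np.ndarray]) -> None:
    for p, w in zip(net.parameters(), weights):
        p["value"][...] = w


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _take(x, idx):
    if isinstance(x, tuple):
        return tuple(a[idx] for a in x)
    return x[idx]


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stopped_epoch: int = 0


def fit(
    net: Layer,
    x_train,
    y_train: np.ndarray,
    x_val,
    y_val: np.ndarray,
    lr: float = 1e-3,
    max_epochs: int = 100,
    patience: int = 10,
    batch_size: int = 256,
    seed: int = 0,
) -> History:
    """Adam training with early stopping on validation loss.

    Stops after ``patience`` consecutive epochs without a strict decrease of
    the validation loss and restores the best-epoch weights. ``x_*`` is a
    single array or a tuple of arrays (multi-channel input).
    """
    n = y_train.shape[0]
    if n == 0 or y_val.shape[0] == 0:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(seed)
    optimizer = Adam(net.parameters(), lr=lr)
    history = History()
    best_loss = np.inf
    best_weights = get_weights(net)
    since_best = 0
    for epoch in range(1, max_epochs + 1):
        losses = []
        for idx in _batches(n, batch_size, rng):
            z = net.forward(_take(x_train, idx), train=True)
            loss, grad = bce_with_logits(z, y_train[idx])
            net.backward(grad)
            optimizer.step()
            losses.append(loss)
        z_val = net.forward(x_val, train=False)
        val_loss, _ = bce_with_logits(z_val, y_val)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = get_weights(net)
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                history.stopped_epoch = epoch
                break
    else:
        history.stopped_epoch = max_epochs
    set_weights(net, best_weights)
    return history


def predict_proba(net: Layer, x, batch_size: int = 1024) -> np.ndarray:
    """Sigmoid outputs at inference (dropout off)."""
    n = x[0].shape[0] if isinstance(x, tuple) else x.shape[0]
    outs = []
    for start in range(0, n, batch_size):
        idx = slice(start, start + batch_size)
        outs.append(sigmoid(net.forward(_take(x, idx), train=False)))
    return np.vstack(outs)
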