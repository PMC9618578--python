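"""Minimal feed-forward neural network machinery (NumPy, manual backprop).

Implements exactly what the transfer model needs: dense layers with ReLU
activations and inverted dropout, a sequential MLP with forward/backward
passes (including gradients with respect to the *input*, required both for
the joint loss and for integrated gradients), and the Adam optimizer.
All randomness flows through explicit ``numpy.random.Generator`` objects so
identical seeds give bit-identical training runs.
"""

from __future__ import annotations

import numpy as np


class Dense:
    """Affine layer ``Y = X W + b`` with uniform fan-in initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._X: np.ndarray | None = None

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        self._X = X
        return X @ self.W + self.b

    def backward(self, dY: np.ndarray) -> np.ndarray:
        self.dW += self._X.T @ dY
        self.db += dY.sum(axis=0)
        return dY @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        self._mask = X > 0
        return X * self._mask

    def backward(self, dY: np.ndarray) -> np.ndarray:
        return dY * self._mask

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return X
        self._mask = (self.rng.random(X.shape) >= self.p) / (1.0 - self.p)
        return X * self._mask

    def backward(self, dY: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dY
        return dY * self._mask

    def params(self):
        return []


class MLP:
    """A sequential stack of layers with manual backpropagation."""

    def __init__(self, layers: list):
        self.layers = layers

    @classmethod
    def build(
        cls,
        dims: list[int],
        rng: np.random.Generator,
        *,
        final_relu: bool = False,
        dropout: float = 0.0,
        dropout_rng: np.random.Generator | None = None,
    ) -> "MLP":
        """Dense/ReLU stack through ``dims``; hidden layers get ReLU (and
        optionally dropout), the final Dense is linear unless ``final_relu``."""
        layers: list = []
        for i in range(len(dims) - 1):
            layers.append(Dense(dims[i], dims[i + 1], rng))
            last = i == len(dims) - 2
            if not last or final_relu:
                layers.append(ReLU())
                if dropout > 0 and not last:
                    layers.append(Dropout(dropout, dropout_rng or rng))
        return cls(layers)

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            X = layer.forward(X, train)
        return X

    __call__ = forward

    def backward(self, dY: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients; return gradient w.r.t. the input."""
        for layer in reversed(self.layers):
            dY = layer.backward(dY)
        return dY

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params(), weights):
            p[...] = w


class Adam:
    """Adam optimizer over a list of MLPs."""

    def __init__(
        self,
        models: list[MLP],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.models = models
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for model in models for p, _ in model.params()]
        self.v = [np.zeros_like(p) for model in models for p, _ in model.params()]

    def zero_grad(self) -> None:
        for model in self.models:
            model.zero_grad()

    def step(self) -> None:
        self.t += 1
        i = 0
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for model in self.models:
            for p, g in model.params():
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
                p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
                i += 1


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
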