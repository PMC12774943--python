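"""Minimal fully-connected network machinery (numpy, reverse-mode by hand).

The self-supervised fitting network is tiny (three 18-unit layers), so it is
implemented directly: dense layers, ELU activation, inverted dropout and the
Adam optimiser.  Shapes are (batch, features) throughout.  All randomness
flows through an explicit ``numpy.random.Generator`` so runs are reproducible
bit-for-bit.  (The protocol selector trains many network pairs in lock-step
and carries its own stacked-tensor implementation.)
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "ELU", "Dropout", "Sequential", "Adam"]


class Layer:
    trainable: bool = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_and_grads(self):
        return []


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style init, appropriate for the rectified/ELU hidden units used here
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.w.T

    def params_and_grads(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._x: np.ndarray | None = None

    def forward(self, x, train):
        self._x = x
        return np.where(x > 0, x, self.alpha * np.expm1(x))

    def backward(self, grad):
        x = self._x
        return grad * np.where(x > 0, 1.0, self.alpha * np.exp(x))


class Dropout(Layer):
    """Inverted dropout; identity when p == 0 or at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential:
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for _, g in self.params_and_grads():
            g.fill(0.0)

    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_and_grads())
        return out

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params_and_grads()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (p, _), s in zip(self.params_and_grads(), state):
            p[...] = s


class Adam:
    """Adam optimiser over one or more Sequential models."""

    def __init__(self, models, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.models = list(models)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self._pairs()]
        self.v = [np.zeros_like(p) for p, _ in self._pairs()]

    def _pairs(self):
        out = []
        for model in self.models:
            out.extend(model.params_and_grads())
        return out

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self._pairs()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for model in self.models:
            model.zero_grad()
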