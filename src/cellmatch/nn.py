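"""Dense neural-network primitives with explicit backpropagation.

The package trains a small variational autoencoder on desk-scale cohorts, so
the layers are plain float64 numpy: each ``forward`` caches what ``backward``
needs, ``backward`` accumulates parameter gradients and returns the gradient
with respect to its input. Gradient correctness is asserted against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Linear", "ReLU", "MLP", "Adam"]


class Linear:
    """Affine layer ``x @ W + b`` with He/Xavier-style seeded init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 weight_scale: float | None = None):
        if weight_scale is None:
            weight_scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, weight_scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MLP:
    """Linear/ReLU stack; the final Linear has no activation.

    Hidden layers use He init (ReLU-facing); the output layer uses a smaller
    1/sqrt(n_in) scale so untrained heads start near zero output.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers: list = []
        n_affine = len(sizes) - 1
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = i == n_affine - 1
            scale = np.sqrt(1.0 / a) if last else np.sqrt(2.0 / a)
            self.layers.append(Linear(a, b, rng, scale))
            if not last:
                self.layers.append(ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def linears(self) -> list[Linear]:
        return [l for l in self.layers if isinstance(l, Linear)]

    @property
    def params(self):
        return [p for l in self.linears for p in l.params]

    @property
    def grads(self):
        return [g for l in self.linears for g in l.grads]

    def zero_grad(self) -> None:
        for l in self.linears:
            l.zero_grad()


class Adam:
    """Adam on a fixed list of parameter arrays, updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
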