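"""Neural-network building blocks on top of the autodiff core.

Dense and LSTM layers hold :class:`Tensor` parameters; :class:`Adam`
implements the optimiser with optional global-norm gradient clipping.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor


def glorot_uniform(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    """Affine transformation y = x W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(glorot_uniform(rng, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.W) + self.b

    @property
    def parameters(self):
        return [self.W, self.b]


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


class LSTM:
    """Single unidirectional LSTM layer (gate order i, f, g, o).

    Input kernels are Glorot-uniform; the recurrent kernel of each gate is
    orthogonal, which preserves gradient norms through time and helps the
    layer learn long-range structure. The forget-gate bias is initialised to
    one, the standard trick that keeps memory open early in training.
    """

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.n_in = n_in
        self.n_units = n_units
        W = np.empty((n_in + n_units, 4 * n_units))
        W[:n_in] = glorot_uniform(rng, (n_in, 4 * n_units))
        for g in range(4):
            W[n_in:, g * n_units : (g + 1) * n_units] = orthogonal(rng, n_units)
        self.W = Tensor(W, requires_grad=True)
        b = np.zeros(4 * n_units)
        b[n_units : 2 * n_units] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x, reverse: bool = False) -> Tensor:
        return ad.lstm(x, self.W, self.b, reverse=reverse)

    def step(self, x_t: np.ndarray, h: np.ndarray, c: np.ndarray):
        """Plain-NumPy single step (used for ancestral sampling)."""
        H = self.n_units
        z = np.concatenate([x_t, h], axis=-1) @ self.W.value + self.b.value
        i = ad._sigmoid(z[..., :H])
        f = ad._sigmoid(z[..., H : 2 * H])
        g = np.tanh(z[..., 2 * H : 3 * H])
        o = ad._sigmoid(z[..., 3 * H :])
        c = f * c + i * g
        h = o * np.tanh(c)
        return h, c

    @property
    def parameters(self):
        return [self.W, self.b]


class BiLSTM:
    """Bidirectional LSTM: forward and reverse passes concatenated."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.fwd = LSTM(n_in, n_units, rng)
        self.bwd = LSTM(n_in, n_units, rng)

    def __call__(self, x) -> Tensor:
        return ad.concatenate([self.fwd(x), self.bwd(x, reverse=True)], axis=-1)

    @property
    def parameters(self):
        return self.fwd.parameters + self.bwd.parameters


class Adam:
    """Adam optimiser with optional global-norm gradient clipping."""

    def __init__(
        self,
        parameters,
        learning_rate: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        gradient_clip: float | None = None,
    ):
        self.parameters = list(parameters)
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.gradient_clip = gradient_clip
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.parameters]
        self._v = [np.zeros_like(p.value) for p in self.parameters]

    def step(self):
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.value)
            for p in self.parameters
        ]
        if self.gradient_clip is not None:
            norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
            if norm > self.gradient_clip:
                scale = self.gradient_clip / (norm + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.parameters, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.parameters:
            p.grad = None


def softplus_inverse(y: float) -> float:
    """Raw value whose softplus is ``y`` (used to initialise constrained params)."""
    return float(y + np.log(-np.expm1(-y)))
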