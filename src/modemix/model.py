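"""The generative mixture-of-modes model.

Data are modelled as draws from a multivariate normal whose moments are a
time-varying linear mixture of J static spatial modes,

    m_t = sum_j alpha_jt mu_j,      C_t = sum_j alpha_jt D_j,

with simplex-valued mixing coefficients alpha_t = softmax(theta_t / tau).
The unconstrained logits theta_t follow a recurrent prior: a unidirectional
LSTM (the *model RNN*) reads the sampled logit history and predicts the mean
and standard deviation of the next logit, giving the model a memory far
beyond a Markov chain's single step. Mode covariances are parameterised by
Cholesky factors with a softplus-plus-epsilon diagonal, so they remain
strictly positive definite throughout training; the softmax temperature tau
is a trainable positive scalar controlling how mixed (high tau) or mutually
exclusive (low tau) the modes are.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from ._nn import LSTM, Dense, softplus_inverse

__all__ = [
    "ModeModelConfig",
    "ModeModel",
    "build_covariances",
    "softmax_mixing",
    "mix_moments",
]


def build_covariances(
    cholesky_vectors: np.ndarray, epsilon: float = 1e-6
) -> np.ndarray:
    """Reconstruct covariances D_j = L_j L_j' from flat Cholesky parameters.

    Each vector of length n(n+1)/2 fills a lower-triangular factor; the
    diagonal passes through softplus and gains ``epsilon``, guaranteeing
    strict positive definiteness.
    """
    cholesky_vectors = np.atleast_2d(np.asarray(cholesky_vectors, dtype=float))
    m = cholesky_vectors.shape[-1]
    n = int((np.sqrt(8 * m + 1) - 1) / 2)
    if n * (n + 1) // 2 != m:
        raise ValueError(f"{m} is not a triangular number of Cholesky entries")
    L = ad.build_cholesky(Tensor(cholesky_vectors), n, epsilon).value
    return L @ np.swapaxes(L, -1, -2)


def softmax_mixing(theta: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """Temperature-scaled softmax along the last axis (max-stabilised)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = np.asarray(theta, dtype=float) / temperature
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mix_moments(
    alpha: np.ndarray,
    means: np.ndarray,
    covariances: np.ndarray,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous moments (m_t, C_t) of the mode mixture.

    ``alpha`` rows must lie on the simplex (checked to ``tol``); C_t is then
    positive semi-definite whenever every D_j is.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < -tol) or np.any(
        np.abs(alpha.sum(axis=-1) - 1.0) > max(tol, 1e-8)
    ):
        raise ValueError("mixing coefficients are off the simplex")
    m = alpha @ np.asarray(means, dtype=float)
    C = np.einsum("...j,jmn->...mn", alpha, np.asarray(covariances, dtype=float))
    return m, C


@dataclasses.dataclass
class ModeModelConfig:
    n_modes: int = 3
    n_channels: int = 11
    model_rnn_units: int = 64
    learn_means: bool = False
    learn_temperature: bool = True
    initial_temperature: float = 1.0
    cholesky_epsilon: float = 1e-6
    covariance_init: str = "data_split"  # or "identity_jitter"
    seed: int = 0


class ModeModel:
    """Trainable parameters of the generative model.

    Holds the mode means (frozen at zero by default — appropriate both for
    the zero-mean simulations and for time-delay-embedded data where spectral
    content should live in the covariances), the flat Cholesky parameters of
    the mode covariances, the softmax temperature (softplus-parameterised so
    it stays positive) and the model-RNN weights with its affine heads.
    """

    def __init__(self, config: ModeModelConfig, data: np.ndarray | None = None):
        self.config = config
        J, n = config.n_modes, config.n_channels
        rng = np.random.default_rng(config.seed)

        rows, cols = np.tril_indices(n)
        diag_mask = rows == cols
        flat = np.zeros((J, n * (n + 1) // 2))
        if config.covariance_init == "identity_jitter":
            flat[:, diag_mask] = softplus_inverse(1.0)
            flat += 0.05 * rng.standard_normal(flat.shape)
        elif config.covariance_init in ("data_split", "random_window"):
            if data is None:
                raise ValueError(f"{config.covariance_init} initialisation needs data")
            data = np.asarray(data, dtype=float)
            if config.covariance_init == "data_split":
                # split the time axis into J contiguous blocks
                segs = np.array_split(data, J, axis=1)
            else:
                # J short random windows: snapshots of different local regimes
                T = data.shape[1]
                w = min(T, max(100, 5 * n))
                starts = rng.integers(0, T - w + 1, size=J)
                segs = [data[:, s : s + w] for s in starts]
            for j, seg in enumerate(segs):
                cov = np.cov(seg) + 1e-4 * np.eye(n)
                L = np.linalg.cholesky(cov)
                vals = L[rows, cols].copy()
                d = np.maximum(vals[diag_mask] - config.cholesky_epsilon, 1e-6)
                vals[diag_mask] = np.log(np.expm1(d))
                flat[j] = vals
            flat += 0.01 * rng.standard_normal(flat.shape)
        else:
            raise ValueError(f"unknown covariance_init {config.covariance_init!r}")
        self.cholesky_flat = Tensor(flat, requires_grad=True)

        self.means = Tensor(
            np.zeros((J, n)), requires_grad=config.learn_means
        )
        self._raw_temperature = Tensor(
            np.array(softplus_inverse(config.initial_temperature)),
            requires_grad=config.learn_temperature,
        )
        self.model_rnn = LSTM(J, config.model_rnn_units, rng)
        self.g_mu = Dense(config.model_rnn_units, J, rng)
        self.g_sigma = Dense(config.model_rnn_units, J, rng)

    # -- parameter access ----------------------------------------------------
    @property
    def parameters(self) -> list[Tensor]:
        params = [self.cholesky_flat]
        if self.means.requires_grad:
            params.append(self.means)
        if self._raw_temperature.requires_grad:
            params.append(self._raw_temperature)
        params += self.model_rnn.parameters
        params += self.g_mu.parameters + self.g_sigma.parameters
        return params

    def temperature_tensor(self) -> Tensor:
        return ad.softplus(self._raw_temperature)

    @property
    def temperature(self) -> float:
        return float(self.temperature_tensor().value)

    def covariances_tensor(self) -> Tensor:
        L = ad.build_cholesky(
            self.cholesky_flat, self.config.n_channels, self.config.cholesky_epsilon
        )
        return ad.matmul(L, ad.transpose_last2(L))

    @property
    def covariances(self) -> np.ndarray:
        return self.covariances_tensor().value

    # -- recurrent prior -------------------------------------------------------
    def prior_moments(self, theta) -> tuple[Tensor, Tensor]:
        """Prior (mu_theta, sigma_theta) for t = 2..N given logits theta_1:N.

        ``theta`` is (batch, N, J); the model RNN consumes theta_1:N-1 and the
        affine heads map its hidden state to the moments of the next logit,
        so the output at position t depends only on inputs before t + 1
        (causality). Returns tensors of shape (batch, N - 1, J); the first
        time point of a window has no recurrent prior.
        """
        theta = theta if isinstance(theta, Tensor) else Tensor(np.asarray(theta, float))
        h = self.model_rnn(theta[:, :-1])
        mu = self.g_mu(h)
        sigma = ad.softplus(self.g_sigma(h)) + 1e-6
        return mu, sigma

    # -- ancestral sampling ------------------------------------------------------
    def sample_generative(
        self, n_samples: int, seed: int = 0, sigma_scale: float = 1.0
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sample (theta, alpha, x) ancestrally from the generative model.

        theta_1 ~ N(0, I) (the first step has no recurrent history); each
        subsequent logit is drawn from the LSTM-predicted Gaussian, then
        alpha_t = softmax(theta_t / tau) and x_t ~ N(m_t, C_t).
        ``sigma_scale`` rescales the prior standard deviation (0 gives the
        deterministic mean trajectory).
        """
        rng = np.random.default_rng(seed)
        J = self.config.n_modes
        H = self.config.model_rnn_units
        theta = np.empty((n_samples, J))
        theta[0] = rng.standard_normal(J)
        h = np.zeros(H)
        c = np.zeros(H)
        for t in range(1, n_samples):
            h, c = self.model_rnn.step(theta[t - 1], h, c)
            mu = h @ self.g_mu.W.value + self.g_mu.b.value
            sigma = (
                np.logaddexp(0.0, h @ self.g_sigma.W.value + self.g_sigma.b.value)
                + 1e-6
            )
            theta[t] = mu + sigma_scale * sigma * rng.standard_normal(J)
        alpha = softmax_mixing(theta, self.temperature)
        x = _sample_mixture_observations(
            alpha, self.means.value, self.covariances, rng
        )
        return theta, alpha, x


def _sample_mixture_observations(alpha, means, covs, rng) -> np.ndarray:
    m = alpha @ means
    C = np.einsum("tj,jmn->tmn", alpha, covs)
    L = np.linalg.cholesky(C)
    eps = rng.standard_normal(m.shape)
    return (m + np.einsum("tmn,tn->tm", L, eps)).T
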