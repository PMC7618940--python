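"""Synthetic multivariate Gaussian time series with latent mode dynamics.

Two generators are provided, matching the two simulation studies the package
reproduces:

* a hidden semi-Markov model (HSMM) whose state lifetimes are drawn from a
  gamma distribution and whose transition matrix excludes self-transitions —
  mutually exclusive states with long-range temporal structure that a plain
  Markov chain cannot generate;
* a soft mixture whose logits are sine waves of differing amplitude,
  frequency and phase, pushed through a softmax to give ground-truth mixing
  coefficients — genuinely co-activating modes.

Observations are drawn from a multivariate normal whose moments are the
mode mixture m_t = sum_j alpha_jt mu_j, C_t = sum_j alpha_jt D_j.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "HSMMConfig",
    "SineLogitConfig",
    "GroundTruth",
    "sample_hsmm",
    "random_covariances",
    "sample_sine_logits",
    "sample_observations",
    "simulate_hsmm_dataset",
    "simulate_sine_dataset",
    "uniform_transition_matrix",
]


def uniform_transition_matrix(n_states: int) -> np.ndarray:
    """Row-stochastic matrix, uniform over non-self states, zero diagonal."""
    if n_states < 2:
        raise ValueError("need at least 2 states for a zero-diagonal chain")
    P = np.full((n_states, n_states), 1.0 / (n_states - 1))
    np.fill_diagonal(P, 0.0)
    return P


@dataclasses.dataclass
class HSMMConfig:
    """Hidden semi-Markov simulation parameters.

    Lifetimes are gamma distributed (``lifetime_shape``, ``lifetime_scale``
    in samples); the defaults give a mean lifetime of 50 samples. The
    transition matrix must be row stochastic with a zero diagonal so states
    never self-transition (durations live entirely in the gamma law).
    """

    n_states: int = 3
    n_samples: int = 25_600
    lifetime_shape: float = 5.0
    lifetime_scale: float = 10.0
    transition_matrix: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.transition_matrix is None:
            self.transition_matrix = uniform_transition_matrix(self.n_states)
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (self.n_states, self.n_states):
            raise ValueError("transition matrix shape does not match n_states")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.diag(P) != 0.0):
            raise ValueError("transition matrix diagonal must be exactly 0")
        if self.lifetime_shape <= 0 or self.lifetime_scale <= 0:
            raise ValueError("gamma lifetime parameters must be positive")
        self.transition_matrix = P


@dataclasses.dataclass
class SineLogitConfig:
    """Sine-wave logits for the soft-mixture simulation.

    Each mode's logit is amplitude * sin(2*pi*frequency*t + phase) with
    frequency in cycles per sample. When a parameter list is omitted the
    documented defaults apply: amplitudes uniform in [1, 2.5] and phases
    uniform in [0, 2*pi), both seeded; frequencies evenly spaced over
    [0.5, 2] cycles per 1000 samples — slow oscillations that are genuinely
    distinct per mode (random frequency draws can nearly collide, which makes
    two modes' logits collinear and the mixture unidentifiable).
    """

    n_modes: int = 6
    n_samples: int = 25_600
    amplitudes: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    phases: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        if self.amplitudes is None:
            self.amplitudes = rng.uniform(1.0, 2.5, self.n_modes)
        if self.frequencies is None:
            self.frequencies = (
                np.linspace(0.5e-3, 2.0e-3, self.n_modes)
                if self.n_modes > 1
                else np.array([1.0e-3])
            )
        if self.phases is None:
            self.phases = rng.uniform(0.0, 2.0 * np.pi, self.n_modes)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        for name in ("amplitudes", "frequencies", "phases"):
            if len(getattr(self, name)) != self.n_modes:
                raise ValueError(f"{name} must have one entry per mode")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        if len(np.unique(self.frequencies)) != self.n_modes:
            raise ValueError("frequencies must be distinct")


@dataclasses.dataclass
class GroundTruth:
    """A simulated dataset together with everything that generated it."""

    data: np.ndarray  # (n_channels, n_samples)
    covariances: np.ndarray  # (n_modes, n_channels, n_channels)
    means: np.ndarray  # (n_modes, n_channels)
    state_course: np.ndarray | None = None  # (n_samples,) integer states
    alpha: np.ndarray | None = None  # (n_samples, n_modes) mixing series
    logits: np.ndarray | None = None  # (n_samples, n_modes)
    config: object | None = None

    @property
    def mixing(self) -> np.ndarray:
        """Mixing series as (n_samples, n_modes); one-hot for state courses."""
        if self.alpha is not None:
            return self.alpha
        n_modes = self.covariances.shape[0]
        return np.eye(n_modes)[self.state_course]


def sample_hsmm(config: HSMMConfig) -> np.ndarray:
    """Sample a state time course with gamma-distributed lifetimes.

    Lifetimes are rounded to the nearest integer and floored at one sample;
    the final segment is truncated to fit ``n_samples``. Consecutive segments
    always have distinct states because self-transitions are excluded.
    """
    rng = np.random.default_rng(config.seed)
    course = np.empty(config.n_samples, dtype=np.int64)
    state = int(rng.integers(config.n_states))
    t = 0
    while t < config.n_samples:
        lifetime = max(
            1,
            int(
                np.rint(
                    rng.gamma(config.lifetime_shape, config.lifetime_scale)
                )
            ),
        )
        end = min(t + lifetime, config.n_samples)
        course[t:end] = state
        t = end
        state = int(rng.choice(config.n_states, p=config.transition_matrix[state]))
    return course


def random_covariances(
    n_modes: int, n_channels: int, seed: int = 0
) -> np.ndarray:
    """Random symmetric strictly positive-definite mode covariances.

    D = W W' / n_channels + 0.1 I with W a standard-normal square draw:
    strictly positive definite by construction and well separated across
    modes, reproducible from the seed.
    """
    if n_modes < 1 or n_channels < 1:
        raise ValueError("n_modes and n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    covs = np.empty((n_modes, n_channels, n_channels))
    for j in range(n_modes):
        W = rng.standard_normal((n_channels, n_channels))
        covs[j] = W @ W.T / n_channels + 0.1 * np.eye(n_channels)
    return covs


def sample_sine_logits(config: SineLogitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sine-wave logits and their softmax mixing coefficients.

    Returns (logits, alpha), both (n_samples, n_modes); each row of alpha is
    on the simplex.
    """
    t = np.arange(config.n_samples)[:, None]
    theta = config.amplitudes * np.sin(
        2.0 * np.pi * config.frequencies * t + config.phases
    )
    z = theta - theta.max(axis=1, keepdims=True)
    e = np.exp(z)
    alpha = e / e.sum(axis=1, keepdims=True)
    return theta, alpha


def sample_observations(
    mixing: np.ndarray,
    means: np.ndarray,
    covariances: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Draw x_t ~ N(m_t, C_t) from the mode mixture at each time point.

    ``mixing`` is (n_samples, n_modes): rows of a soft mixing series, or
    one-hot rows for a mutually exclusive state course. Returns data as
    (n_channels, n_samples).
    """
    mixing = np.asarray(mixing, dtype=float)
    means = np.asarray(means, dtype=float)
    covariances = np.asarray(covariances, dtype=float)
    if mixing.ndim == 1:  # integer state course
        mixing = np.eye(covariances.shape[0])[mixing.astype(int)]
    if mixing.shape[1] != covariances.shape[0] or means.shape != covariances.shape[:2]:
        raise ValueError("mixing, means and covariances dimensions disagree")
    rng = np.random.default_rng(seed)
    n_samples, _ = mixing.shape
    n_channels = covariances.shape[1]
    m = mixing @ means
    C = np.einsum("tj,jmn->tmn", mixing, covariances)
    L = np.linalg.cholesky(C)
    eps = rng.standard_normal((n_samples, n_channels))
    x = m + np.einsum("tmn,tn->tm", L, eps)
    return x.T


def simulate_hsmm_dataset(
    n_states: int = 3,
    n_channels: int = 11,
    n_samples: int = 25_600,
    lifetime_shape: float = 5.0,
    lifetime_scale: float = 10.0,
    transition_matrix: np.ndarray | None = None,
    seed: int = 0,
) -> GroundTruth:
    """End-to-end HSMM study dataset: zero-mean modes, random covariances."""
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    config = HSMMConfig(
        n_states=n_states,
        n_samples=n_samples,
        lifetime_shape=lifetime_shape,
        lifetime_scale=lifetime_scale,
        transition_matrix=transition_matrix,
        seed=seeds[0],
    )
    course = sample_hsmm(config)
    covs = random_covariances(n_states, n_channels, seed=seeds[1])
    means = np.zeros((n_states, n_channels))
    data = sample_observations(course, means, covs, seed=seeds[2])
    return GroundTruth(
        data=data,
        covariances=covs,
        means=means,
        state_course=course,
        config=config,
    )


def simulate_sine_dataset(
    n_modes: int = 6,
    n_channels: int = 80,
    n_samples: int = 25_600,
    seed: int = 0,
) -> GroundTruth:
    """End-to-end soft-mixture study dataset with sine-wave logits."""
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    config = SineLogitConfig(n_modes=n_modes, n_samples=n_samples, seed=seeds[0])
    theta, alpha = sample_sine_logits(config)
    covs = random_covariances(n_modes, n_channels, seed=seeds[1])
    means = np.zeros((n_modes, n_channels))
    data = sample_observations(alpha, means, covs, seed=seeds[2])
    return GroundTruth(
        data=data,
        covariances=covs,
        means=means,
        alpha=alpha,
        logits=theta,
        config=config,
    )
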