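"""Baseline Gaussian-observation hidden Markov model.

The comparison model: mutually exclusive states with multivariate-normal
emissions, fitted by EM (Baum-Welch with the standard scaling trick), decoded
by Viterbi or forward-backward posteriors, and sampled as a Markov chain.
State means are frozen at zero by default for parity with the mixture model's
zero-mean configuration — the states then differ only in covariance, so the
fit is initialised from the covariances of random data windows to break the
otherwise exact state symmetry. A state whose responsibility mass collapses
is re-seeded from a fresh random window (with a warning) rather than being
allowed to produce a degenerate covariance.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg

__all__ = ["HMMParams", "fit_hmm", "decode_states", "sample_hmm", "state_posteriors"]


@dataclasses.dataclass
class HMMParams:
    """Fitted HMM parameters and the EM log-likelihood history."""

    n_states: int
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihoods: np.ndarray  # EM history, non-decreasing
    converged: bool


def _emission_logprob(X: np.ndarray, means: np.ndarray, covs: np.ndarray):
    """Per-state Gaussian log-densities, (T, K)."""
    T, n = X.shape
    K = covs.shape[0]
    out = np.empty((T, K))
    for j in range(K):
        L = linalg.cholesky(covs[j], lower=True)
        z = linalg.solve_triangular(L, (X - means[j]).T, lower=True)
        out[:, j] = -0.5 * (
            np.sum(z**2, axis=0)
            + n * np.log(2.0 * np.pi)
        ) - np.log(np.diag(L)).sum()
    return out


def _forward_backward(log_b, startprob, A):
    """Scaled forward-backward; returns (gamma, xi_sum, log-likelihood)."""
    T, K = log_b.shape
    c = log_b.max(axis=1, keepdims=True)
    b = np.exp(log_b - c)
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = startprob * b[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    loglik = float(np.log(scale).sum() + c.sum())
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = A * (alpha[:-1].T @ (b[1:] * beta[1:] / scale[1:, None]))
    return gamma, xi_sum, loglik


def _init_covariances(X, n_states, rng, jitter=1e-4):
    """Per-state covariances of random contiguous windows of the data."""
    T, n = X.shape
    w = min(T, max(100, 5 * n))
    covs = np.empty((n_states, n, n))
    for j in range(n_states):
        start = int(rng.integers(0, T - w + 1))
        covs[j] = np.cov(X[start : start + w].T) + jitter * np.eye(n)
    return covs


def fit_hmm(
    data: np.ndarray,
    n_states: int,
    seed: int = 0,
    learn_means: bool = False,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> HMMParams:
    """Fit a Gaussian-observation HMM by EM on (channels, time) data.

    EM stops when the relative log-likelihood change drops below ``tol`` or
    after ``max_iter`` iterations; the log-likelihood history is
    non-decreasing (a defining property of EM). With ``learn_means=False``
    only transitions, start probabilities and full covariances are updated.
    """
    X = np.asarray(data, dtype=float).T
    T, n = X.shape
    if T <= n_states:
        raise ValueError("data must be longer than the number of states")
    rng = np.random.default_rng(seed)
    startprob = np.full(n_states, 1.0 / n_states)
    A = rng.dirichlet(5.0 * np.ones(n_states), size=n_states)
    means = (
        X[rng.choice(T, n_states, replace=False)]
        if learn_means
        else np.zeros((n_states, n))
    )
    covs = _init_covariances(X, n_states, rng)

    history = []
    converged = False
    for _ in range(max_iter):
        log_b = _emission_logprob(X, means, covs)
        gamma, xi_sum, loglik = _forward_backward(log_b, startprob, A)
        history.append(loglik)
        if len(history) > 1:
            delta = history[-1] - history[-2]
            if abs(delta) < tol * abs(history[-2]):
                converged = True
                break
        # M step
        startprob = gamma[0] / gamma[0].sum()
        A = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        Nj = gamma.sum(axis=0)
        for j in range(n_states):
            if Nj[j] < n + 1:  # state died: re-seed instead of degenerating
                warnings.warn(
                    f"state {j} lost its responsibility mass; re-seeded"
                )
                covs[j] = _init_covariances(X, 1, rng)[0]
                continue
            if learn_means:
                means[j] = gamma[:, j] @ X / Nj[j]
            R = X - means[j]
            S = (R * gamma[:, j, None]).T @ R / Nj[j]
            eigmin = np.linalg.eigvalsh(S).min()
            if eigmin < 1e-10:
                warnings.warn(f"degenerate covariance of state {j}; jitter added")
                S += (1e-8 - min(eigmin, 0.0)) * np.eye(n)
            covs[j] = S

    return HMMParams(
        n_states=n_states,
        transition_matrix=A,
        initial_distribution=startprob,
        means=means,
        covariances=covs,
        log_likelihoods=np.asarray(history),
        converged=converged,
    )


def decode_states(
    params: HMMParams, data: np.ndarray, method: str = "viterbi"
) -> np.ndarray:
    """Decode a state course from (channels, time) data.

    ``method='viterbi'`` returns the jointly most probable path;
    ``method='posterior'`` the per-time-point argmax of the forward-backward
    posteriors.
    """
    X = np.asarray(data, dtype=float).T
    log_b = _emission_logprob(X, params.means, params.covariances)
    if method == "posterior":
        gamma, _, _ = _forward_backward(
            log_b, params.initial_distribution, params.transition_matrix
        )
        return gamma.argmax(axis=1)
    if method != "viterbi":
        raise ValueError(f"unknown decoding method {method!r}")
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition_matrix)
        logpi = np.log(params.initial_distribution)
    T, K = log_b.shape
    delta = logpi + log_b[0]
    back = np.empty((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + log_b[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_log_probability(params: HMMParams, data: np.ndarray, path: np.ndarray):
    """Joint log-probability of a given state path and the data."""
    X = np.asarray(data, dtype=float).T
    path = np.asarray(path, dtype=int)
    log_b = _emission_logprob(X, params.means, params.covariances)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition_matrix)
        logpi = np.log(params.initial_distribution)
    lp = logpi[path[0]] + log_b[0, path[0]]
    lp += logA[path[:-1], path[1:]].sum() + log_b[np.arange(1, len(path)), path[1:]].sum()
    return float(lp)


def state_posteriors(params: HMMParams, data: np.ndarray) -> np.ndarray:
    """Forward-backward posteriors, (time, states); rows sum to one."""
    X = np.asarray(data, dtype=float).T
    log_b = _emission_logprob(X, params.means, params.covariances)
    gamma, _, _ = _forward_backward(
        log_b, params.initial_distribution, params.transition_matrix
    )
    return gamma


def sample_hmm(
    params: HMMParams, n_samples: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a state course and Gaussian emissions; returns (states, data).

    Markov-chain state sampling followed by per-state Gaussian emission;
    lifetimes of a sampled course are geometric by construction. ``data`` is
    (channels, time).
    """
    rng = np.random.default_rng(seed)
    K = params.n_states
    states = np.empty(n_samples, dtype=int)
    states[0] = rng.choice(K, p=params.initial_distribution)
    for t in range(1, n_samples):
        states[t] = rng.choice(K, p=params.transition_matrix[states[t - 1]])
    chols = np.linalg.cholesky(params.covariances)
    eps = rng.standard_normal((n_samples, params.means.shape[1]))
    data = params.means[states] + np.einsum(
        "tmn,tn->tm", chols[states], eps
    )
    return states, data.T
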