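"""Amortised variational inference for the mixture-of-modes model.

A bidirectional LSTM (the *inference RNN*) maps each window of observed data
to a diagonal-Gaussian variational posterior over the logits at every time
point. Training minimises the variational free energy

    F = -LL + annealing * KL,

where LL is the log-likelihood of the window under moments built from a
single reparameterized posterior sample path, and KL is the closed-form
divergence between the posterior and the recurrent prior evaluated on that
same sample path (summed from the second time point of each window — the
first has no recurrent history). The KL term is annealed from ~0 to 1 over
the early epochs with a sharpness-parameterised tanh schedule, which keeps
the posterior from collapsing onto the prior before the observation model
has learnt anything. Optimisation is Adam with optional global-norm gradient
clipping; optionally several short "multi-start" runs are raced and the
lowest-loss start is trained to completion.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Tensor
from ._nn import Adam, BiLSTM, Dense
from .model import ModeModel, ModeModelConfig

__all__ = [
    "TrainingConfig",
    "LossReport",
    "InferenceRNN",
    "TrainedModel",
    "infer_posterior",
    "reparam_sample",
    "gaussian_kl",
    "kl_annealing_factor",
    "free_energy",
    "train",
    "map_mixing",
]


@dataclasses.dataclass
class TrainingConfig:
    """Hyperparameters of one training run (defaults match the simulations)."""

    n_modes: int = 3
    sequence_length: int = 200
    inference_units: int = 64
    model_units: int = 64
    kl_annealing_sharpness: float = 10.0
    kl_annealing_epochs: int = 100
    n_epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 0.01
    gradient_clip: float | None = None
    n_multi_starts: int = 1
    multi_start_epochs: int = 0
    learn_means: bool = False
    learn_temperature: bool = True
    covariance_init: str = "data_split"
    seed: int = 0

    def __post_init__(self):
        if self.kl_annealing_epochs > self.n_epochs:
            raise ValueError("kl_annealing_epochs cannot exceed n_epochs")
        for name in ("sequence_length", "n_epochs", "batch_size", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class LossReport:
    """Free energy and its components for one batch or epoch."""

    free_energy: float
    log_likelihood: float
    kl: float
    annealing: float

    def __post_init__(self):
        # identity on the stored components
        resid = self.free_energy - (-self.log_likelihood + self.annealing * self.kl)
        if abs(resid) > 1e-6 * max(1.0, abs(self.free_energy)):
            raise ValueError("free energy does not decompose as -LL + a*KL")


class InferenceRNN:
    """Bidirectional LSTM with affine heads producing posterior moments."""

    def __init__(
        self, n_channels: int, n_modes: int, n_units: int, seed: int = 0
    ):
        rng = np.random.default_rng(seed)
        self.n_modes = n_modes
        self.blstm = BiLSTM(n_channels, n_units, rng)
        self.f_m = Dense(2 * n_units, n_modes, rng)
        self.f_s = Dense(2 * n_units, n_modes, rng)

    def __call__(self, x) -> tuple[Tensor, Tensor]:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        h = self.blstm(x)
        m = self.f_m(h)
        s = ad.softplus(self.f_s(h)) + 1e-6
        return m, s

    @property
    def parameters(self):
        return self.blstm.parameters + self.f_m.parameters + self.f_s.parameters


def infer_posterior(x: np.ndarray, inference_rnn: InferenceRNN):
    """Posterior moments (m, s) for a window batch (batch, time, channels)."""
    m, s = inference_rnn(np.asarray(x, dtype=float))
    return m.value, s.value


def reparam_sample(m, s, seed: int | None = None, eps: np.ndarray | None = None):
    """theta = m + s * eps with eps ~ N(0, I) (the reparameterization trick)."""
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    if eps is None:
        eps = np.random.default_rng(seed).standard_normal(m.shape)
    return m + s * eps


def gaussian_kl(m, s, mu, sigma) -> np.ndarray:
    """Closed-form KL( N(m, s^2) || N(mu, sigma^2) ), summed over the last axis."""
    m, s = np.asarray(m, float), np.asarray(s, float)
    mu, sigma = np.asarray(mu, float), np.asarray(sigma, float)
    if np.any(s <= 0) or np.any(sigma <= 0):
        raise ValueError("standard deviations must be positive")
    kl = (
        np.log(sigma / s) + (s**2 + (m - mu) ** 2) / (2.0 * sigma**2) - 0.5
    )
    return kl.sum(axis=-1)


def kl_annealing_factor(
    epoch: int, sharpness: float = 10.0, n_annealing_epochs: int = 100
) -> float:
    """Annealing weight in [0, 1]: a tanh sigmoid of given sharpness.

    Rises monotonically over ``n_annealing_epochs`` epochs and is exactly 1
    afterwards.
    """
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    if n_annealing_epochs <= 0 or epoch >= n_annealing_epochs:
        return 1.0
    return float(
        0.5 * (np.tanh(sharpness * (epoch / n_annealing_epochs - 0.5)) + 1.0)
    )


def _kl_tensor(qm, qs, pm, ps) -> Tensor:
    """Closed-form diagonal-Gaussian KL as an autodiff expression (summed)."""
    var_ratio = (qs * qs) / (ps * ps)
    delta = (qm - pm) / ps
    kl = 0.5 * (var_ratio + delta * delta - 1.0) + ad.log(ps) - ad.log(qs)
    return ad.tsum(kl)


def free_energy(
    x: np.ndarray,
    mode_model: ModeModel,
    inference_rnn: InferenceRNN,
    annealing: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, LossReport]:
    """Single-sample estimate of the variational free energy of a window batch.

    Draws one reparameterized sample path theta per window, evaluates the
    data log-likelihood under the mixture moments of that path, and the KL
    between the posterior and the recurrent prior fed the same sampled path
    (from the second time point on). Returns the loss tensor (for backward)
    and a float report.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, dtype=float)
    post_m, post_s = inference_rnn(x)
    eps = rng.standard_normal(post_m.value.shape)
    theta = post_m + post_s * Tensor(eps)  # reparameterized sample
    tau = mode_model.temperature_tensor()
    alpha = ad.softmax(theta / tau)
    covs = mode_model.covariances_tensor()
    nll = ad.gaussian_mixture_nll(x, alpha, mode_model.means, covs)
    prior_mu, prior_sigma = mode_model.prior_moments(theta)
    kl = _kl_tensor(
        post_m[:, 1:], post_s[:, 1:], prior_mu, prior_sigma
    )
    loss = nll + float(annealing) * kl
    report = LossReport(
        free_energy=float(loss.value),
        log_likelihood=-float(nll.value),
        kl=float(kl.value),
        annealing=float(annealing),
    )
    return loss, report


@dataclasses.dataclass
class TrainedModel:
    """A trained generative model, its inference network and loss history."""

    mode_model: ModeModel
    inference_rnn: InferenceRNN
    history: pd.DataFrame
    config: TrainingConfig

    @property
    def free_energy(self) -> float:
        return float(self.history["free_energy"].iloc[-1])


def _make_windows(data: np.ndarray, sequence_length: int) -> np.ndarray:
    """Split (channels, time) data into non-overlapping (W, N, channels)."""
    data = np.asarray(data, dtype=float)
    n_channels, T = data.shape
    n_windows = T // sequence_length
    if n_windows == 0:
        raise ValueError("data shorter than one sequence")
    trimmed = data[:, : n_windows * sequence_length]
    return trimmed.T.reshape(n_windows, sequence_length, n_channels)


def _run_epochs(
    windows, mode_model, inference_rnn, optimiser, config, rng, first_epoch, last_epoch
):
    rows = []
    n_windows = windows.shape[0]
    for epoch in range(first_epoch, last_epoch):
        annealing = kl_annealing_factor(
            epoch, config.kl_annealing_sharpness, config.kl_annealing_epochs
        )
        order = rng.permutation(n_windows)
        f_sum = ll_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, n_windows, config.batch_size):
            batch = windows[order[start : start + config.batch_size]]
            optimiser.zero_grad()
            loss, report = free_energy(
                batch, mode_model, inference_rnn, annealing, rng
            )
            if not np.isfinite(loss.value):
                raise FloatingPointError(
                    f"free energy diverged (epoch {epoch})"
                )
            loss.backward()
            optimiser.step()
            f_sum += report.free_energy
            ll_sum += report.log_likelihood
            kl_sum += report.kl
            n_batches += 1
        rows.append(
            {
                "epoch": epoch,
                "free_energy": f_sum / n_batches,
                "log_likelihood": ll_sum / n_batches,
                "kl": kl_sum / n_batches,
                "annealing": annealing,
            }
        )
    return rows


def _init_start(data, config: TrainingConfig, seed: int):
    n_channels = data.shape[0]
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    mode_model = ModeModel(
        ModeModelConfig(
            n_modes=config.n_modes,
            n_channels=n_channels,
            model_rnn_units=config.model_units,
            learn_means=config.learn_means,
            learn_temperature=config.learn_temperature,
            covariance_init=config.covariance_init,
            seed=seeds[0],
        ),
        data=data,
    )
    inference_rnn = InferenceRNN(
        n_channels, config.n_modes, config.inference_units, seed=seeds[1]
    )
    optimiser = Adam(
        mode_model.parameters + inference_rnn.parameters,
        learning_rate=config.learning_rate,
        gradient_clip=config.gradient_clip,
    )
    rng = np.random.default_rng(seeds[2])
    return mode_model, inference_rnn, optimiser, rng


def train(data: np.ndarray, config: TrainingConfig) -> TrainedModel:
    """Train the model on (channels, time) data; returns the fitted model.

    With ``n_multi_starts > 1``, each start trains for ``multi_start_epochs``
    epochs from its own initialisation; the start with the lowest epoch-mean
    free energy continues to ``n_epochs``. A start whose loss diverges is
    abandoned (an error is raised only if every start diverges).
    """
    windows = _make_windows(data, config.sequence_length)
    start_seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(config.seed).spawn(
            max(1, config.n_multi_starts)
        )
    ]

    if config.n_multi_starts > 1 and config.multi_start_epochs > 0:
        candidates = []
        for seed in start_seeds:
            state = _init_start(data, config, seed)
            try:
                rows = _run_epochs(
                    windows, *state[:3], config, state[3], 0,
                    config.multi_start_epochs,
                )
            except FloatingPointError:
                continue
            candidates.append((rows[-1]["free_energy"], rows, state))
        if not candidates:
            raise FloatingPointError("every training start diverged")
        _, rows, state = min(candidates, key=lambda c: c[0])
        first_epoch = config.multi_start_epochs
    else:
        state = _init_start(data, config, start_seeds[0])
        rows = []
        first_epoch = 0

    mode_model, inference_rnn, optimiser, rng = state
    rows += _run_epochs(
        windows, mode_model, inference_rnn, optimiser, config, rng,
        first_epoch, config.n_epochs,
    )
    history = pd.DataFrame(rows)
    return TrainedModel(mode_model, inference_rnn, history, config)


def map_mixing(
    mode_model: ModeModel,
    inference_rnn: InferenceRNN,
    data: np.ndarray,
    sequence_length: int | None = None,
) -> np.ndarray:
    """Maximum a posteriori mixing coefficients for a whole recording.

    Windows the data, takes the posterior mean (the mode of the Gaussian)
    at each time point and maps it through the temperature-scaled softmax:
    alpha_t = softmax(m_theta_t / tau). A trailing partial window is covered
    by re-running the final full-length window. Returns (time, modes).
    """
    data = np.asarray(data, dtype=float)
    n_channels, T = data.shape
    N = sequence_length or T
    windows = _make_windows(data, min(N, T))
    m, _ = infer_posterior(windows, inference_rnn)
    theta = m.reshape(-1, m.shape[-1])
    covered = theta.shape[0]
    if covered < T:
        tail, _ = infer_posterior(data[:, T - min(N, T):].T[None], inference_rnn)
        theta = np.concatenate([theta, tail[0, -(T - covered):]], axis=0)
    from .model import softmax_mixing

    return softmax_mixing(theta, mode_model.temperature)
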