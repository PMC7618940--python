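"""Post-hoc statistics on inferred latent time courses.

Everything downstream of model fitting lives here: trace-weighted mixing
coefficients, GMM-based activation detection, lifetime/interval/fractional-
occupancy summaries, mode matching and the dice coefficient, the affine-
invariant Riemannian distance between covariances and its use as a
time-varying reconstruction error, PSDs of mixing time courses, regression
spectra (a least-squares decomposition of the data's spectrogram onto the
mixing coefficients) and evoked-response epoching with a sign-flip
max-statistic permutation test.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg, signal, stats
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import GaussianMixture

__all__ = [
    "ActivationCourse",
    "SummaryStats",
    "SpectralDecomposition",
    "weighted_alphas",
    "detect_activations",
    "summary_statistics",
    "match_modes",
    "dice_coefficient",
    "riemannian_distance",
    "rv_coefficient",
    "timevarying_cov_error",
    "mixing_psd",
    "regression_spectra",
    "epoch_evoked",
]


# ---------------------------------------------------------------------------
# mixing-series transformations
# ---------------------------------------------------------------------------


def weighted_alphas(alpha: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    """Trace-weighted, renormalised mixing coefficients.

    A mode with a small raw coefficient can still dominate the instantaneous
    covariance if its mode covariance is large; weighting by Tr(D_j) and
    renormalising restores the sum-to-one constraint while reflecting each
    mode's actual contribution.
    """
    alpha = np.asarray(alpha, dtype=float)
    traces = np.trace(np.asarray(covariances, dtype=float), axis1=-2, axis2=-1)
    w = alpha * traces
    return w / w.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# activation detection and summary statistics
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ActivationCourse:
    """Binary per-mode activity series at a given sampling frequency."""

    active: np.ndarray  # (time, modes) bool
    sampling_frequency: float
    thresholds: np.ndarray | None = None


def detect_activations(
    series: np.ndarray,
    sampling_frequency: float = 1.0,
    seed: int = 0,
) -> ActivationCourse:
    """Label each time point active/inactive with a two-component GMM.

    A univariate two-Gaussian mixture is fitted per mode; a point is active
    when the responsibility of the higher-mean component exceeds 0.5. A
    near-constant series cannot support the fit and is marked never-active
    (with a warning).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    T, J = series.shape
    if T < 100:
        raise ValueError("need at least 100 time points to fit the GMM")
    active = np.zeros((T, J), dtype=bool)
    thresholds = np.full(J, np.nan)
    for j in range(J):
        x = series[:, j]
        if np.std(x) < 1e-10:
            warnings.warn(f"mode {j} is (near-)constant; marked never active")
            continue
        gmm = GaussianMixture(n_components=2, random_state=seed, n_init=2)
        gmm.fit(x[:, None])
        hi = int(np.argmax(gmm.means_.ravel()))
        resp = gmm.predict_proba(x[:, None])[:, hi]
        active[:, j] = resp > 0.5
        if active[:, j].any() and (~active[:, j]).any():
            thresholds[j] = 0.5 * (
                x[active[:, j]].min() + x[~active[:, j]].max()
            )
    return ActivationCourse(active, sampling_frequency, thresholds)


@dataclasses.dataclass
class SummaryStats:
    """Per-mode temporal summaries (times in seconds)."""

    lifetimes: list  # list over modes of arrays of activation durations
    intervals: list  # durations of inactive gaps between activations
    fractional_occupancy: np.ndarray  # (modes,)
    sampling_frequency: float


def _runs(binary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run values, run lengths) of a 1-D boolean series."""
    edges = np.flatnonzero(np.diff(binary.astype(int))) + 1
    starts = np.concatenate([[0], edges])
    lengths = np.diff(np.concatenate([starts, [binary.size]]))
    return binary[starts], lengths


def summary_statistics(activations: ActivationCourse) -> SummaryStats:
    """Lifetimes, interval times and fractional occupancy per mode."""
    A = np.asarray(activations.active, dtype=bool)
    if A.ndim == 1:
        A = A[:, None]
    fs = activations.sampling_frequency
    lifetimes, intervals = [], []
    for j in range(A.shape[1]):
        vals, lens = _runs(A[:, j])
        lifetimes.append(lens[vals] / fs)
        # an interval is an inactive run *between* activations
        inactive = lens[~vals]
        if A[:, j].any():
            if not A[0, j]:
                inactive = inactive[1:]
            if not A[-1, j]:
                inactive = inactive[:-1]
        else:
            inactive = inactive[:0]
        intervals.append(inactive / fs)
    fo = A.mean(axis=0)
    return SummaryStats(lifetimes, intervals, fo, fs)


# ---------------------------------------------------------------------------
# matching and comparison metrics
# ---------------------------------------------------------------------------


def match_modes(
    series_a: np.ndarray,
    series_b: np.ndarray,
    covariances_a: np.ndarray | None = None,
    covariances_b: np.ndarray | None = None,
    criterion: str = "correlation",
) -> np.ndarray:
    """Permutation aligning the modes of ``series_b`` to ``series_a``.

    Hungarian assignment maximising either the summed per-pair time-course
    correlation (default) or the RV coefficient between mode covariances.
    Returns ``perm`` such that ``series_b[:, perm]`` matches ``series_a``.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("mode counts differ")
    J = a.shape[1]
    score = np.empty((J, J))
    if criterion == "correlation":
        az = a - a.mean(axis=0)
        bz = b - b.mean(axis=0)
        sa = np.sqrt((az**2).sum(axis=0))
        sb = np.sqrt((bz**2).sum(axis=0))
        sa[sa == 0] = 1.0
        sb[sb == 0] = 1.0
        score = (az.T @ bz) / np.outer(sa, sb)
    elif criterion == "rv":
        for i in range(J):
            for j in range(J):
                score[i, j] = rv_coefficient(covariances_a[i], covariances_b[j])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    rows, cols = linear_sum_assignment(-score)
    perm = np.empty(J, dtype=int)
    perm[rows] = cols
    return perm


def rv_coefficient(A: np.ndarray, B: np.ndarray) -> float:
    """RV coefficient between two symmetric matrices (1 = proportional)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    return float(
        np.sum(A * B) / np.sqrt(np.sum(A * A) * np.sum(B * B))
    )


def _as_state_course(course: np.ndarray) -> np.ndarray:
    course = np.asarray(course)
    if course.ndim == 2:  # soft mixture -> argmax binarisation
        return course.argmax(axis=1)
    return course.astype(int)


def dice_coefficient(inferred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap of two mutually exclusive state courses after matching.

    Soft mixtures are binarised by argmax first; states are aligned by
    Hungarian assignment on per-state indicator overlap, so the result is
    invariant to relabelling. For exclusive courses this equals the fraction
    of matching time points.
    """
    a = _as_state_course(inferred)
    b = _as_state_course(truth)
    if a.shape[0] != b.shape[0]:
        raise ValueError("state courses have different lengths")
    n_states = int(max(a.max(), b.max())) + 1
    one_a = np.eye(n_states)[a]
    one_b = np.eye(n_states)[b]
    overlap = one_a.T @ one_b  # (states, states) co-occurrence counts
    rows, cols = linear_sum_assignment(-overlap)
    inter = overlap[rows, cols].sum()
    return float(2.0 * inter / (one_a.sum() + one_b.sum()))


def riemannian_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between SPD matrices.

    d(A, B) = sqrt(sum_i log^2 lambda_i) with lambda_i the generalised
    eigenvalues of (B, A); symmetric, zero iff A = B, and invariant under
    congruence A -> M A M'. Eigenvalues are floored at 1e-10.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    for M in (A, B):
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("inputs must be symmetric")
    lam = linalg.eigvalsh(B, A)
    lam = np.maximum(lam, 1e-10)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def timevarying_cov_error(
    mixing: np.ndarray,
    covariances: np.ndarray,
    truth_cov: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Riemannian distance between reconstructed and true C_t at each t.

    ``mixing`` may be a soft series (time, modes) or an integer state course
    (one-hot reconstruction). ``truth_cov`` is (time, n, n). Returns the
    per-time-point distances and their mean.
    """
    mixing = np.asarray(mixing)
    covariances = np.asarray(covariances, dtype=float)
    if mixing.ndim == 1:
        mixing = np.eye(covariances.shape[0])[mixing.astype(int)]
    recon = np.einsum("tj,jmn->tmn", mixing, covariances)
    truth_cov = np.asarray(truth_cov, dtype=float)
    if recon.shape != truth_cov.shape:
        raise ValueError("reconstruction and truth shapes differ")
    d = np.array(
        [riemannian_distance(truth_cov[t], recon[t]) for t in range(len(recon))]
    )
    return d, float(d.mean())


def compare_cov_errors(d_a: np.ndarray, d_b: np.ndarray):
    """Paired t-test between two per-time-point distance series."""
    d_a = np.asarray(d_a, float)
    d_b = np.asarray(d_b, float)
    if np.allclose(d_a, d_b):
        return 0.0, 1.0  # identical inputs: no difference to test
    res = stats.ttest_rel(d_a, d_b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def mixing_psd(
    series: np.ndarray,
    sampling_frequency: float,
    window_seconds: float | None = None,
    fo_window_seconds: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of each mode's (standardised) mixing time course.

    Binary state courses are first converted to a windowed fractional
    occupancy (default 200 ms window). Each series is z-transformed across
    time before the PSD. Returns (frequencies, psd) with psd (modes, freqs).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if set(np.unique(series)).issubset({0.0, 1.0}):
        w = max(1, int(round(fo_window_seconds * sampling_frequency)))
        kernel = np.ones(w) / w
        series = np.column_stack(
            [np.convolve(series[:, j], kernel, mode="same") for j in range(series.shape[1])]
        )
    mu = series.mean(axis=0)
    sd = series.std(axis=0)
    sd[sd == 0] = 1.0
    z = (series - mu) / sd
    nperseg = (
        int(window_seconds * sampling_frequency)
        if window_seconds
        else min(len(z), 2048)
    )
    f, psd = signal.welch(z, fs=sampling_frequency, nperseg=nperseg, axis=0)
    return f, psd.T


@dataclasses.dataclass
class SpectralDecomposition:
    """Least-squares decomposition of a spectrogram onto mixing coefficients."""

    frequencies: np.ndarray  # (F,)
    mean_psd: np.ndarray  # P0(f), (F,)
    mode_psd: np.ndarray  # Pj(f), (modes, F)
    residuals: np.ndarray  # eps_t(f), (frames, F)
    frame_times: np.ndarray  # (frames,) seconds
    reconstruction_error: np.ndarray  # per-frame error as % of power
    mean_reconstruction_error: float


def regression_spectra(
    data: np.ndarray,
    alpha: np.ndarray,
    sampling_frequency: float,
    window_seconds: float = 2.0,
    overlap: float = 0.5,
) -> SpectralDecomposition:
    """Regress the data's spectrogram on the mixing coefficients.

    A Hann-tapered short-time spectrogram S_t(f) (averaged across channels)
    is modelled per frequency as S_t(f) = P0(f) + sum_j alpha_jt Pj(f) +
    eps_t(f) by ordinary least squares, with the mixing coefficients
    averaged within each frame. P0 is the mean PSD, Pj a mode's deviation
    from it. The per-frame reconstruction error is reported as a percentage
    of the frame's frequency-averaged power. A (near-)constant mixing series
    makes the design rank deficient; a pseudo-inverse solution is returned
    with a warning.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    alpha = np.asarray(alpha, dtype=float)
    nperseg = int(window_seconds * sampling_frequency)
    noverlap = int(nperseg * overlap)
    f, t_frames, S = signal.spectrogram(
        data,
        fs=sampling_frequency,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        axis=-1,
        mode="psd",
    )
    S = S.mean(axis=0).T  # (frames, freqs), channel average
    # align alpha with frame centres by within-frame averaging
    step = nperseg - noverlap
    frames = []
    for k in range(S.shape[0]):
        start = k * step
        frames.append(alpha[start : start + nperseg].mean(axis=0))
    A = np.asarray(frames)
    design = np.column_stack([np.ones(len(A)), A])
    rank = np.linalg.matrix_rank(design)
    # simplex-valued alpha always makes the intercept collinear with the mode
    # columns (they sum to one); the expected rank is therefore n_modes, and
    # only a rank below that signals a genuinely degenerate design. lstsq
    # returns the minimum-norm solution either way, so P0 + Pj stays
    # identifiable even though P0 and Pj separately are not.
    if rank < alpha.shape[1]:
        warnings.warn("rank-deficient design (constant mixing?); using pseudo-inverse")
    coeffs, *_ = np.linalg.lstsq(design, S, rcond=None)
    P0 = coeffs[0]
    Pj = coeffs[1:]
    resid = S - design @ coeffs
    power = S.mean(axis=1)
    power[power == 0] = 1.0
    err = 100.0 * np.abs(resid).mean(axis=1) / power
    return SpectralDecomposition(
        frequencies=f,
        mean_psd=P0,
        mode_psd=Pj,
        residuals=resid,
        frame_times=t_frames,
        reconstruction_error=err,
        mean_reconstruction_error=float(err.mean()),
    )


# ---------------------------------------------------------------------------
# evoked responses
# ---------------------------------------------------------------------------


def epoch_evoked(
    series: np.ndarray,
    event_times: np.ndarray,
    window: tuple[float, float],
    sampling_frequency: float,
    n_permutations: int = 1000,
    alpha_level: float = 0.05,
    seed: int = 0,
):
    """Trial-averaged evoked response with a sign-flip max-statistic test.

    Epochs ``series`` (time,) or (time, modes) around each event, baseline-
    corrects every trial by its pre-event mean, and averages. Significance is
    assessed per mode by randomly sign-flipping whole trials: the null is the
    distribution of the maximum |t| across time points within a permutation,
    which controls the family-wise error rate across time. Events too close
    to the edges are dropped with a warning.

    Returns (evoked (T, modes), times (T,), significant (T, modes) bool,
    t_observed (T, modes)).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    fs = sampling_frequency
    pre = int(round(-window[0] * fs))
    post = int(round(window[1] * fs))
    if pre < 1:
        raise ValueError("window must start before the event (negative start)")
    trials = []
    dropped = 0
    for ev in np.asarray(event_times, dtype=float):
        c = int(round(ev * fs))
        if c - pre < 0 or c + post > series.shape[0]:
            dropped += 1
            continue
        ep = series[c - pre : c + post].copy()
        ep -= ep[:pre].mean(axis=0)  # baseline correction
        trials.append(ep)
    if dropped:
        warnings.warn(f"{dropped} event(s) too close to the edges were dropped")
    if not trials:
        raise ValueError("no usable trials")
    E = np.asarray(trials)  # (trials, T, modes)
    n_trials = E.shape[0]
    if n_trials < 2:
        warnings.warn("fewer than two usable trials; significance not assessed")
        evoked = E.mean(axis=0)
        times = np.arange(-pre, post) / fs
        zeros = np.zeros_like(evoked)
        return evoked, times, zeros.astype(bool), zeros
    evoked = E.mean(axis=0)
    sd = E.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf  # constant across trials -> t = 0
    t_obs = evoked / (sd / np.sqrt(n_trials))
    rng = np.random.default_rng(seed)
    max_null = np.empty((n_permutations, E.shape[2]))
    for p in range(n_permutations):
        flips = rng.choice([-1.0, 1.0], size=n_trials)[:, None, None]
        Ef = E * flips
        m = Ef.mean(axis=0)
        s = Ef.std(axis=0, ddof=1)
        s[s == 0] = np.inf
        tperm = m / (s / np.sqrt(n_trials))
        max_null[p] = np.abs(tperm).max(axis=0)
    thresh = np.quantile(max_null, 1.0 - alpha_level, axis=0)
    significant = np.abs(t_obs) > thresh
    times = (np.arange(-pre, post)) / fs
    return evoked, times, significant, t_obs
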