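"""Data preparation: time-delay embedding, PCA reduction, standardisation.

The pipeline order is fixed — embed, then PCA, then z-transform across time.
Time-delay embedding adds lagged copies of each channel so that the channel
covariance of the embedded data carries the autocorrelation function (and
hence spectral content) of the original signals; PCA tames the resulting
dimensionality; standardisation is always the final step.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "PreparedDataset",
    "time_delay_embed",
    "fit_apply_pca",
    "standardise",
    "prepare",
]


@dataclasses.dataclass
class PreparedDataset:
    """Prepared data plus the constants needed to reuse the transform."""

    data: np.ndarray  # (n_components, n_samples)
    n_embeddings: int
    pca_components: np.ndarray | None  # (embedded_channels, n_components)
    explained_variance: np.ndarray | None
    channel_means: np.ndarray | None = None
    channel_stds: np.ndarray | None = None
    provenance: dict | None = None


def time_delay_embed(data: np.ndarray, n_embeddings: int) -> np.ndarray:
    """Stack time-lagged copies of every channel.

    Lags are symmetric about zero (-floor(n/2) .. +floor(n/2) for odd n).
    Edge time points without a full lag context are trimmed, so the output
    has ``channels * n_embeddings`` rows and ``T - n_embeddings + 1`` columns.
    Rows are grouped by channel, lags in increasing order within a channel.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_channels, T = data.shape
    if n_embeddings < 1:
        raise ValueError("n_embeddings must be >= 1")
    if T <= n_embeddings:
        raise ValueError(
            f"series length {T} too short for {n_embeddings} embeddings"
        )
    half = n_embeddings // 2
    lags = np.arange(n_embeddings) - half  # symmetric window
    n_out = T - n_embeddings + 1
    out = np.empty((n_channels * n_embeddings, n_out))
    # column t of the output corresponds to original time index t + half
    for c in range(n_channels):
        for k, lag in enumerate(lags):
            start = half + lag
            out[c * n_embeddings + k] = data[c, start : start + n_out]
    return out


def fit_apply_pca(
    embedded: np.ndarray, n_components: int
) -> tuple[PreparedDataset, np.ndarray]:
    """PCA on the channel covariance of the (concatenated) embedded data.

    The projection is the matrix of leading covariance eigenvectors, ordered
    by decreasing explained variance; reduced data = projection' @ embedded.
    No whitening is applied and the channel means are not restored after
    projection.
    """
    embedded = np.asarray(embedded, dtype=float)
    n_rows = embedded.shape[0]
    if n_components > n_rows:
        raise ValueError("n_components exceeds the number of rows")
    centred = embedded - embedded.mean(axis=1, keepdims=True)
    cov = centred @ centred.T / embedded.shape[1]
    rank = np.linalg.matrix_rank(cov)
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds data rank {rank}")
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:n_components]
    projection = eigvec[:, order]
    explained = eigval[order]
    reduced = projection.T @ embedded
    ds = PreparedDataset(
        data=reduced,
        n_embeddings=0,
        pca_components=projection,
        explained_variance=explained,
    )
    return ds, reduced


def standardise(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-transform each row across time (population standard deviation).

    Returns (standardised data, means, stds). A zero-variance row is an
    error naming the offending row.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    means = data.mean(axis=1)
    stds = data.std(axis=1)
    bad = np.flatnonzero(stds == 0.0)
    if bad.size:
        raise ValueError(f"zero-variance row(s): {bad.tolist()}")
    z = (data - means[:, None]) / stds[:, None]
    return z, means, stds


def prepare(
    data: np.ndarray,
    n_embeddings: int = 15,
    n_pca_components: int | None = 80,
) -> PreparedDataset:
    """Full pipeline: time-delay embed, PCA, standardise (in that order)."""
    embedded = time_delay_embed(data, n_embeddings) if n_embeddings > 1 else np.atleast_2d(data)
    if n_pca_components is not None:
        ds, reduced = fit_apply_pca(embedded, n_pca_components)
    else:
        ds = PreparedDataset(
            data=embedded, n_embeddings=n_embeddings,
            pca_components=None, explained_variance=None,
        )
        reduced = embedded
    z, means, stds = standardise(reduced)
    ds.data = z
    ds.n_embeddings = n_embeddings
    ds.channel_means = means
    ds.channel_stds = stds
    ds.provenance = {
        "n_embeddings": n_embeddings,
        "n_pca_components": n_pca_components,
    }
    return ds
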