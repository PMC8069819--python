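"""Single-trial functional connectivity measures.

Three pairwise channel-dependency estimators operate on each
(trial, band, window) segment:

* GFC — Gaussian-kernel functional connectivity,
  ``exp(-||x_c - x_c'||^2 / (2 sigma^2))``, with the bandwidth ``sigma``
  set by the median heuristic: the median of the pairwise Euclidean
  channel distances within each (trial, band, window) split, averaged
  over all training splits.
* CCF — cross-correlation coefficient: the Pearson correlation of the
  two windowed series.
* PLV — phase-locking value: the modulus of the time-averaged complex
  phase difference, with instantaneous phase from the analytic
  (Hilbert) signal of each windowed channel.

Per-trial values over all (band, window, channel-pair) splits are
stacked into a :class:`ConnectivityTensor` and vectorized band-major
into the feature matrix that feeds sparse relevance selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from sklearn.base import BaseEstimator, TransformerMixin

from .filterbank import TFSegments

__all__ = [
    "SigmaEstimate",
    "ConnectivityTensor",
    "pair_index",
    "pairwise_distance_tensor",
    "median_sigma",
    "gaussian_kernel_fc",
    "cross_correlation_fc",
    "phase_locking_fc",
    "connectivity_tensor",
    "connectivity_matrices",
    "vectorize",
    "devectorize",
    "feature_index_map",
    "ConnectivityTransformer",
]

MEASURES = ("gfc", "ccf", "plv")


@dataclass(frozen=True)
class SigmaEstimate:
    """Gaussian-kernel bandwidth with a note on which trials it pooled."""

    sigma: float
    scope: str = "all-trials"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive and finite; got {self.sigma}")


@dataclass
class ConnectivityTensor:
    """Per-(trial, band, window, pair) connectivity values, upper triangle only."""

    values: np.ndarray  # (R, B, W, P)
    measure: str
    pairs: list[tuple[int, int]]
    bands: tuple[tuple[float, float], ...]
    window_starts: np.ndarray
    labels: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        # invert P = C(C-1)/2
        p = self.values.shape[-1]
        return int(round((1 + np.sqrt(1 + 8 * p)) / 2))


def pair_index(n_channels: int) -> list[tuple[int, int]]:
    """Lexicographic (c, c') with c < c'; bijective with the strict upper triangle."""
    if n_channels < 2:
        raise ValueError(f"need at least 2 channels; got {n_channels}")
    return [
        (c, cp) for c in range(n_channels - 1) for cp in range(c + 1, n_channels)
    ]


def _triu_indices(n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_channels, k=1)


def pairwise_distance_tensor(segments: TFSegments) -> np.ndarray:
    """Euclidean distances ||x_c - x_c'|| per split: (R, B, W, P).

    Computed through the per-window Gram matrix, which makes a per-fold
    re-estimation of the kernel bandwidth essentially free.
    """
    x = segments.values  # (R, B, W, C, L)
    gram = np.einsum("rbwcl,rbwdl->rbwcd", x, x)
    sq = np.einsum("rbwcc->rbwc", gram)
    d2 = sq[..., :, None] + sq[..., None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)
    iu, ju = _triu_indices(x.shape[3])
    return np.sqrt(d2[..., iu, ju])


def median_sigma(
    segments: TFSegments, train_mask: np.ndarray | None = None
) -> SigmaEstimate:
    """Median heuristic bandwidth: median distance per split, mean over splits."""
    dist = pairwise_distance_tensor(segments)
    if train_mask is not None:
        train_mask = np.asarray(train_mask)
        if train_mask.dtype == bool:
            if not train_mask.any():
                raise ValueError("training mask selects no trials")
            dist = dist[train_mask]
        else:
            if len(train_mask) == 0:
                raise ValueError("training mask selects no trials")
            dist = dist[train_mask]
    sigma = float(np.mean(np.median(dist, axis=-1)))
    if not sigma > 0:
        raise ValueError(
            "median pairwise distance is zero: degenerate (e.g. all-zero) input"
        )
    scope = "all-trials" if train_mask is None else f"{dist.shape[0]}-train-trials"
    return SigmaEstimate(sigma=sigma, scope=scope)


def _check_window(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError(f"expected a (C>=2, L) window; got shape {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("window contains non-finite samples")
    return x


def gaussian_kernel_fc(x: np.ndarray, sigma: SigmaEstimate | float) -> np.ndarray:
    """Gaussian-kernel connectivity matrix exp(-||x_c - x_c'||^2 / 2 sigma^2)."""
    x = _check_window(x)
    s = sigma.sigma if isinstance(sigma, SigmaEstimate) else float(sigma)
    if not s > 0:
        raise ValueError(f"sigma must be positive; got {s}")
    diff2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-diff2 / (2.0 * s * s))


def cross_correlation_fc(x: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the windowed channel series."""
    x = _check_window(x)
    sd = x.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance channel(s) {zero.tolist()} in window")
    xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = xs @ xs.T / x.shape[1]
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def instantaneous_phases(x: np.ndarray) -> np.ndarray:
    """Per-channel instantaneous phase (radians in (-pi, pi]) via the analytic signal."""
    x = _check_window(x)
    if x.shape[1] < 8:
        raise ValueError("analytic-signal phase needs a window of at least 8 samples")
    sd = x.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"constant channel(s) {zero.tolist()}: phase undefined")
    return np.angle(hilbert(x, axis=-1))


def phase_locking_fc(x: np.ndarray) -> np.ndarray:
    """PLV matrix: modulus of the window-averaged complex phase difference."""
    phases = instantaneous_phases(x)
    z = np.exp(1j * phases)
    plv = np.abs(z @ z.conj().T) / x.shape[1]
    np.clip(plv, 0.0, 1.0, out=plv)
    np.fill_diagonal(plv, 1.0)
    return plv


def _gfc_values(segments: TFSegments, sigma: float) -> np.ndarray:
    dist = pairwise_distance_tensor(segments)
    return np.exp(-(dist**2) / (2.0 * sigma * sigma))


def _ccf_values(segments: TFSegments) -> np.ndarray:
    x = segments.values
    sd = x.std(axis=-1)
    if (sd == 0).any():
        idx = np.argwhere(sd == 0)[0]
        raise ValueError(
            f"zero-variance channel at (trial, band, window, channel)={tuple(idx)}"
        )
    xs = (x - x.mean(axis=-1, keepdims=True)) / sd[..., None]
    corr = np.einsum("rbwcl,rbwdl->rbwcd", xs, xs) / x.shape[-1]
    iu, ju = _triu_indices(x.shape[3])
    return np.clip(corr[..., iu, ju], -1.0, 1.0)


def _plv_values(segments: TFSegments) -> np.ndarray:
    x = segments.values
    sd = x.std(axis=-1)
    if (sd == 0).any():
        idx = np.argwhere(sd == 0)[0]
        raise ValueError(
            f"constant channel at (trial, band, window, channel)={tuple(idx)}"
        )
    z = np.exp(1j * np.angle(hilbert(x, axis=-1)))
    m = np.abs(np.einsum("rbwcl,rbwdl->rbwcd", z, z.conj())) / x.shape[-1]
    iu, ju = _triu_indices(x.shape[3])
    return np.clip(m[..., iu, ju], 0.0, 1.0)


def connectivity_tensor(
    segments: TFSegments,
    measure: str = "gfc",
    sigma: SigmaEstimate | float | None = None,
) -> ConnectivityTensor:
    """Fill connectivity values for every (trial, band, window, pair) split."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if measure == "gfc":
        if sigma is None:
            raise ValueError("the Gaussian-kernel measure requires a sigma estimate")
        s = sigma.sigma if isinstance(sigma, SigmaEstimate) else float(sigma)
        values = _gfc_values(segments, s)
    elif measure == "ccf":
        values = _ccf_values(segments)
    else:
        values = _plv_values(segments)
    return ConnectivityTensor(
        values=values,
        measure=measure,
        pairs=pair_index(segments.n_channels),
        bands=segments.bands,
        window_starts=segments.window_starts,
        labels=segments.labels,
    )


def connectivity_matrices(
    segments: TFSegments,
    measure: str = "gfc",
    sigma: SigmaEstimate | float | None = None,
) -> np.ndarray:
    """Full symmetric (R, B, W, C, C) matrices (unit diagonal) for CSP input."""
    ct = connectivity_tensor(segments, measure=measure, sigma=sigma)
    c = segments.n_channels
    iu, ju = _triu_indices(c)
    mats = np.zeros(ct.values.shape[:-1] + (c, c))
    mats[..., iu, ju] = ct.values
    mats[..., ju, iu] = ct.values
    diag = np.arange(c)
    mats[..., diag, diag] = 1.0
    return mats


def feature_index_map(
    n_bands: int, n_windows: int, n_pairs: int
) -> np.ndarray:
    """(D, 3) int array mapping column -> (band, window, pair), band-major."""
    b, w, p = np.meshgrid(
        np.arange(n_bands), np.arange(n_windows), np.arange(n_pairs), indexing="ij"
    )
    return np.stack([b.ravel(), w.ravel(), p.ravel()], axis=1)


def vectorize(t: ConnectivityTensor) -> tuple[np.ndarray, np.ndarray]:
    """Flatten (R, B, W, P) -> (R, B*W*P) with its column index map."""
    r, b, w, p = t.values.shape
    X = t.values.reshape(r, b * w * p)
    return X, feature_index_map(b, w, p)


def devectorize(X: np.ndarray, n_bands: int, n_windows: int, n_pairs: int) -> np.ndarray:
    """Inverse of :func:`vectorize` on the values array."""
    return np.asarray(X).reshape(-1, n_bands, n_windows, n_pairs)


class ConnectivityTransformer(TransformerMixin, BaseEstimator):
    """Segments tensor (R, B, W, C, L) -> connectivity feature matrix (R, D).

    For the Gaussian-kernel measure, :meth:`fit` estimates the bandwidth
    ``sigma_`` with the median heuristic on the training trials only, so
    the transformer is leakage-free inside cross-validation.  CCF and PLV
    have no fitted state.
    """

    def __init__(self, measure: str = "gfc", fs: float = 128.0, tau: float = 1.0):
        self.measure = measure
        self.fs = fs
        self.tau = tau

    def _as_segments(self, X: np.ndarray) -> TFSegments:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 5:
            raise ValueError(f"expected (R, B, W, C, L) tensor; got shape {X.shape}")
        length = X.shape[-1]
        step = max(int(round(length * 0.25)), 1)
        return TFSegments(
            values=X,
            fs=self.fs,
            bands=tuple((0.0, 0.0) for _ in range(X.shape[1])),
            window_starts=np.arange(X.shape[2]) * step,
            tau=self.tau,
        )

    def fit(self, X, y=None):
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        seg = self._as_segments(X)
        if self.measure == "gfc":
            self.sigma_ = median_sigma(seg).sigma
        else:
            self.sigma_ = None
        self.n_features_in_shape_ = X.shape[1:]
        b, w, c = X.shape[1], X.shape[2], X.shape[3]
        self.feature_index_ = feature_index_map(b, w, c * (c - 1) // 2)
        return self

    def transform(self, X) -> np.ndarray:
        seg = self._as_segments(X)
        ct = connectivity_tensor(seg, measure=self.measure, sigma=self.sigma_)
        return vectorize(ct)[0]
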