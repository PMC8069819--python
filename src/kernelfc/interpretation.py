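"""Subject clustering, topographic channel relevance, and top links.

To interpret decoder behaviour across a cohort, each subject's
normalized relevance vector is embedded to 2D with t-SNE, concatenated
with the subject's accuracy (both standardized), and partitioned with
k-means into groups ranked by mean accuracy: Group I (best) through
Group III (worst) — the grouping used to discuss BCI inefficiency.
Channel-level topographies accumulate pair relevance onto channels, and
the strongest pairwise links are those strictly above a percentile
(default 99) of the normalized relevance weights.

Everything here is a pure function of (relevance vectors, accuracies,
seed); plotting is intentionally left out — reports are plain data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .fc import pair_index

__all__ = [
    "ClusterAssignment",
    "TopographyReport",
    "embed_subjects",
    "cluster_subjects",
    "group_switch_matrix",
    "channel_relevance",
    "top_links",
    "topography_report",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass
class ClusterAssignment:
    """Subject -> group (I best accuracy, then II, III), with the embedding."""

    subject_ids: list[str]
    coords: np.ndarray  # (n_subjects, 2)
    groups: list[str]
    group_mean_accuracy: dict[str, float]
    seed: int
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "subject_ids": self.subject_ids,
            "coords": self.coords.tolist(),
            "groups": self.groups,
            "group_mean_accuracy": self.group_mean_accuracy,
            "seed": self.seed,
            "params": self.params,
        }


@dataclass
class TopographyReport:
    """Channel-level accumulated relevance plus supra-percentile links."""

    channel_values: np.ndarray  # (C,), in [0, 1]
    links: list[tuple[int, int, float]]
    percentile: float
    montage: dict | None = None

    def as_dict(self) -> dict:
        return {
            "channel_values": self.channel_values.tolist(),
            "links": [[int(a), int(b), float(w)] for a, b, w in self.links],
            "percentile": self.percentile,
            "montage": self.montage,
        }


def embed_subjects(
    relevance: np.ndarray, seed: int = 0, perplexity: float = 5.0
) -> np.ndarray:
    """t-SNE 2D embedding of l2-normalized subject relevance vectors."""
    relevance = np.asarray(relevance, dtype=np.float64)
    n = relevance.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 subjects to embed; got {n}")
    if perplexity >= n:
        raise ValueError(
            f"perplexity {perplexity} must be below the subject count {n}; "
            f"try perplexity <= {n - 1}"
        )
    norms = np.linalg.norm(relevance, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    rows = relevance / norms
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        method="exact",
    )
    return tsne.fit_transform(rows)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (v - v.mean(axis=0)) / sd


def cluster_subjects(
    coords: np.ndarray,
    accuracies: np.ndarray,
    k: int = 3,
    seed: int = 0,
    subject_ids: list[str] | None = None,
) -> ClusterAssignment:
    """k-means on [standardized coords || standardized accuracy], ranked groups."""
    coords = np.asarray(coords, dtype=np.float64)
    accuracies = np.asarray(accuracies, dtype=np.float64)
    n = coords.shape[0]
    if k > n:
        raise ValueError(f"cannot form k={k} groups from {n} subjects")
    if subject_ids is None:
        subject_ids = [f"S{i:02d}" for i in range(n)]
    features = np.column_stack([_standardize(coords), _standardize(accuracies[:, None])])
    if np.allclose(features, features[0]):
        warnings.warn("all subjects identical: cluster assignment is arbitrary")
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    raw = km.fit_predict(features)
    # relabel clusters by decreasing mean accuracy: I best, then II, ...
    means = [accuracies[raw == c].mean() for c in range(k)]
    order = np.argsort(means)[::-1]
    label_of = {int(c): _ROMAN[rank] for rank, c in enumerate(order)}
    groups = [label_of[int(c)] for c in raw]
    group_mean = {
        _ROMAN[rank]: float(means[c]) for rank, c in enumerate(order)
    }
    return ClusterAssignment(
        subject_ids=list(subject_ids),
        coords=coords,
        groups=groups,
        group_mean_accuracy=group_mean,
        seed=seed,
        params={"k": k, "n_init": 20},
    )


def group_switch_matrix(
    assignments: dict[float, ClusterAssignment],
) -> tuple[np.ndarray, np.ndarray, list[str], list[float]]:
    """Group labels per subject across window lengths, plus switch counts.

    Returns ``(label_matrix, switch_counts, subject_ids, taus)`` with the
    label matrix of shape (subjects, taus) and switch counts over
    adjacent tau columns.
    """
    taus = sorted(assignments)
    if not taus:
        raise ValueError("no assignments given")
    ids = assignments[taus[0]].subject_ids
    for tau in taus[1:]:
        if assignments[tau].subject_ids != ids:
            raise ValueError(f"subject set at tau={tau} mismatches tau={taus[0]}")
    labels = np.array(
        [[assignments[tau].groups[i] for tau in taus] for i in range(len(ids))]
    )
    switches = (labels[:, 1:] != labels[:, :-1]).sum(axis=1)
    return labels, switches, list(ids), taus


def channel_relevance(pair_rel: np.ndarray, n_channels: int) -> np.ndarray:
    """Accumulate pair relevance onto channels, min-max normalized to [0, 1]."""
    pair_rel = np.asarray(pair_rel, dtype=np.float64)
    pairs = pair_index(n_channels)
    if len(pairs) != pair_rel.size:
        raise ValueError(
            f"expected {len(pairs)} pair values for C={n_channels}; got {pair_rel.size}"
        )
    raw = np.zeros(n_channels)
    for (a, b), w in zip(pairs, pair_rel):
        raw[a] += w
        raw[b] += w
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        return (raw - lo) / (hi - lo)
    if hi > 0:
        warnings.warn("uniform channel relevance: reported as constant ones")
        return np.ones(n_channels)
    return raw


def accumulate_channel_relevance(pair_rel: np.ndarray, n_channels: int) -> np.ndarray:
    """Raw (unnormalized) per-channel accumulation; sums to 2x the pair total."""
    pair_rel = np.asarray(pair_rel, dtype=np.float64)
    raw = np.zeros(n_channels)
    for (a, b), w in zip(pair_index(n_channels), pair_rel):
        raw[a] += w
        raw[b] += w
    return raw


def top_links(
    pair_rel: np.ndarray, n_channels: int, percentile: float = 99.0
) -> list[tuple[int, int, float]]:
    """Pairs strictly above the given percentile of the relevance weights.

    The percentile uses linear interpolation; ties at the threshold are
    excluded (an all-equal vector yields no links).  Links are returned
    sorted by weight descending.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError(f"percentile must lie in (0, 100); got {percentile}")
    pair_rel = np.asarray(pair_rel, dtype=np.float64)
    threshold = np.percentile(pair_rel, percentile)
    pairs = pair_index(n_channels)
    links = [
        (a, b, float(w))
        for (a, b), w in zip(pairs, pair_rel)
        if w > threshold
    ]
    links.sort(key=lambda t: (-t[2], t[0], t[1]))
    return links


def topography_report(
    pair_rel: np.ndarray,
    n_channels: int,
    percentile: float = 99.0,
    montage: dict | None = None,
) -> TopographyReport:
    """Bundle channel relevance and top links into one serializable report."""
    return TopographyReport(
        channel_values=channel_relevance(pair_rel, n_channels),
        links=top_links(pair_rel, n_channels, percentile),
        percentile=percentile,
        montage=montage,
    )
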