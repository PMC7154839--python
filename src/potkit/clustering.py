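"""Behavior discovery by clustering interval bag-of-words histograms.

Intervals are represented as L1-normalized bag-of-words histograms of their
quantized PoT descriptors against a k-means codebook. The pairwise distance is
an exponentiated histogram-intersection similarity,

    d(u, v) = -exp(-(1 - HI(b_u, b_v))),

bounded in [-1, -exp(-1)] with identical histograms at -1, which the
multichannel form generalizes to several descriptor channels by averaging the
(1 - HI) terms normalized by their dataset means. Intervals are clustered by
complete-linkage agglomeration on this distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

__all__ = [
    "Codebook",
    "build_codebook",
    "assign",
    "bow",
    "histogram_intersection",
    "interval_distance",
    "multichannel_distance",
    "channel_normalizers",
    "cluster_intervals",
]


@dataclass
class Codebook:
    """k-means centroids quantizing one descriptor channel."""

    centroids: np.ndarray  # (V, dim)
    channel: str = "pot"
    seed: int = 0

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or len(self.centroids) < 2:
            raise ValueError("codebook needs >= 2 finite centroids")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("codebook centroids must be finite")

    @property
    def size(self) -> int:
        return len(self.centroids)


def build_codebook(
    descriptors: np.ndarray,
    V: int = 800,
    restarts: int = 8,
    seed: int = 0,
    channel: str = "pot",
    sample_cap: int = 1_000_000,
) -> Codebook:
    """k-means codebook over a (possibly subsampled) descriptor collection.

    Runs Lloyd's k-means ``restarts`` times with seeds derived from ``seed``
    and keeps the run with the lowest within-cluster sum of squares. At most
    ``sample_cap`` descriptors are used (uniform subsample).
    """
    X = np.asarray(descriptors, dtype=float)
    if X.ndim != 2 or len(X) < V:
        raise ValueError(f"need at least V={V} descriptors, got {len(X) if X.ndim == 2 else 'non-matrix'}")
    rng = np.random.default_rng(seed)
    if len(X) > sample_cap:
        X = X[rng.choice(len(X), size=sample_cap, replace=False)]
    km = KMeans(n_clusters=V, n_init=restarts, random_state=int(rng.integers(2**31 - 1)), algorithm="lloyd")
    km.fit(X)
    return Codebook(km.cluster_centers_, channel=channel, seed=seed)


def assign(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Hard nearest-centroid (Euclidean) codeword index per descriptor."""
    X = np.asarray(descriptors, dtype=float)
    if X.shape[1] != codebook.centroids.shape[1]:
        raise ValueError("descriptor dimension does not match the codebook")
    return pairwise_distances_argmin(X, codebook.centroids)


def bow(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """L1-normalized bag-of-words histogram; all-zero for an empty set."""
    hist = np.zeros(codebook.size)
    X = np.asarray(descriptors, dtype=float)
    if X.size == 0:
        return hist
    words = assign(X, codebook)
    np.add.at(hist, words, 1.0)
    return hist / hist.sum()


def histogram_intersection(b_u: np.ndarray, b_v: np.ndarray) -> float:
    b_u, b_v = np.asarray(b_u, float), np.asarray(b_v, float)
    if b_u.shape != b_v.shape:
        raise ValueError("histograms must have the same size")
    return float(np.minimum(b_u, b_v).sum())


def interval_distance(b_u: np.ndarray, b_v: np.ndarray) -> float:
    """Single-channel distance -exp(-(1 - HI(b_u, b_v)))."""
    return -float(np.exp(-(1.0 - histogram_intersection(b_u, b_v))))


def multichannel_distance(
    channels_u: dict[str, np.ndarray],
    channels_v: dict[str, np.ndarray],
    A: dict[str, float],
) -> float:
    """Multichannel distance -exp(-sum_i (1 - HI_i)/A_i).

    ``A[i]`` is the dataset-average of (1 - HI) for channel i; with a single
    channel and A = 1 this reduces exactly to :func:`interval_distance`.
    """
    if set(channels_u) != set(channels_v) or set(channels_u) != set(A):
        raise ValueError("channel sets disagree")
    expo = 0.0
    for name in channels_u:
        expo += (1.0 - histogram_intersection(channels_u[name], channels_v[name])) / A[name]
    return -float(np.exp(-expo))


def channel_normalizers(bows_per_channel: dict[str, np.ndarray]) -> dict[str, float]:
    """Average (1 - HI) over all item pairs, per channel.

    Computed on the collection being clustered. Degenerate channels where all
    histograms coincide get A = 1 so they contribute zero to the exponent.
    """
    A = {}
    for name, B in bows_per_channel.items():
        B = np.asarray(B, float)
        n = len(B)
        vals = [1.0 - histogram_intersection(B[i], B[j]) for i in range(n) for j in range(i + 1, n)]
        mean = float(np.mean(vals)) if vals else 0.0
        A[name] = mean if mean > 0 else 1.0
    return A


def pairwise_distance_matrix(bows: np.ndarray) -> np.ndarray:
    """Full matrix of single-channel interval distances."""
    B = np.asarray(bows, float)
    n = len(B)
    D = np.empty((n, n))
    for i in range(n):
        hi = np.minimum(B[i][None, :], B).sum(axis=1)
        D[i] = -np.exp(-(1.0 - hi))
    return D


def cluster_intervals(bows: np.ndarray, k: int, distance_matrix: np.ndarray | None = None) -> np.ndarray:
    """Complete-linkage clustering of interval histograms, cut at k clusters.

    Returns 0-based cluster labels. Deterministic given its inputs; the
    linkage implementation resolves exact ties in merge distance by its fixed
    internal scan order.
    """
    n = len(bows)
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, number of intervals]")
    D = pairwise_distance_matrix(bows) if distance_matrix is None else np.asarray(distance_matrix, float)
    # shift to nonnegative: linkage requires a metric-like condensed matrix,
    # and adding a constant does not change complete-linkage merges
    cond = squareform(D - D.min(), checks=False)
    Z = linkage(cond, method="complete")
    return fcluster(Z, t=k, criterion="maxclust") - 1
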