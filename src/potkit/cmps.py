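"""Consistent motion pair (CMP) extraction.

Given two intervals in the same behavior cluster, a CMP is a pair of T-frame
subsequences, one from each interval, whose per-frame motion content matches.
Per-frame bag-of-words histograms (PoT channel, optionally an MBH channel)
give a frame-to-frame distance matrix d_ij; a candidate pair of subsequences
starting at (i, j) is scored by the sum of d along the diagonal,

    s = sum_{t=0}^{T-1} d_{(i+t)(j+t)},

which preserves temporal order. The most negative (most similar) pairs are
returned, with near-duplicate suppression.

The MBH (motion boundary histogram) channel captures flow *derivatives*:
per trajectory point, orientation histograms of the spatial gradients of the
two flow components over a local patch. Constant flow (camera translation)
has zero derivatives, so MBH responds only to motion boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Codebook, assign, channel_normalizers, multichannel_distance
from .io import Interval, Shot
from .pots import PoT

__all__ = [
    "CMP",
    "mbh_descriptors",
    "frame_bows",
    "frame_distance_matrix",
    "extract_cmps",
]

MBH_BINS = 8
MBH_PATCH = 16
EMPTY_FRAME_DISTANCE = -float(np.exp(-1.0))


@dataclass
class CMP:
    """Two T-frame subsequences with consistent foreground motion."""

    interval_p: Interval
    start_i: int  # start frame of the subsequence within interval_p's shot
    interval_q: Interval
    start_j: int
    T: int = 10
    score: float = 0.0

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("CMP length T must be >= 2")
        for iv, s in ((self.interval_p, self.start_i), (self.interval_q, self.start_j)):
            if not (iv.start <= s and s + self.T <= iv.end):
                raise ValueError("CMP subsequence does not fit inside its interval")


def _orientation_histogram(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """8-bin orientation histogram weighted by gradient magnitude."""
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx)  # (-pi, pi]
    bins = np.floor((ang + np.pi) / (2 * np.pi / MBH_BINS)).astype(int) % MBH_BINS
    hist = np.zeros(MBH_BINS)
    np.add.at(hist, bins.ravel(), mag.ravel())
    total = hist.sum()
    return hist / total if total > 0 else hist


def mbh_descriptors(shot: Shot, interval: Interval) -> tuple[np.ndarray, np.ndarray]:
    """Per-trajectory-per-frame MBH descriptors over an interval.

    For every trajectory point inside the interval, the spatial derivatives
    of the flow components u and v are histogrammed over orientation (8 bins
    each) in a 16x16 patch centered at the point, giving a 16-dim descriptor.
    Returns ``(descriptors, frames)``: the (N, 16) matrix and the frame index
    of each descriptor.
    """
    if shot.flow is None:
        raise ValueError("MBH needs dense flow")
    H, W = shot.flow.shape[1:3]
    half = MBH_PATCH // 2
    descs, frames = [], []
    # precompute flow gradients once per frame on demand
    grad_cache: dict[int, tuple] = {}
    for tr in shot.trajectories:
        lo = max(tr.start_frame, interval.start)
        hi = min(tr.end_frame, interval.end, shot.frame_count - 1)
        for t in range(lo, hi):
            if t not in grad_cache:
                u, v = shot.flow[t, :, :, 0], shot.flow[t, :, :, 1]
                gy_u, gx_u = np.gradient(u)
                gy_v, gx_v = np.gradient(v)
                grad_cache[t] = (gx_u, gy_u, gx_v, gy_v)
            gx_u, gy_u, gx_v, gy_v = grad_cache[t]
            x, y = tr.point_at(t)
            x0 = int(np.clip(round(x) - half, 0, W - MBH_PATCH))
            y0 = int(np.clip(round(y) - half, 0, H - MBH_PATCH))
            sl = (slice(y0, y0 + MBH_PATCH), slice(x0, x0 + MBH_PATCH))
            h_u = _orientation_histogram(gx_u[sl], gy_u[sl])
            h_v = _orientation_histogram(gx_v[sl], gy_v[sl])
            descs.append(np.concatenate([h_u, h_v]))
            frames.append(t)
    if not descs:
        return np.empty((0, 2 * MBH_BINS)), np.empty(0, dtype=int)
    return np.stack(descs), np.asarray(frames, dtype=int)


def frame_bows(
    descriptors: np.ndarray,
    frames: np.ndarray,
    codebook: Codebook,
    interval: Interval,
) -> np.ndarray:
    """(len(interval), V) per-frame L1-normalized BoW matrix for one channel.

    Frames with no descriptors get an all-zero row.
    """
    out = np.zeros((len(interval), codebook.size))
    if len(descriptors):
        words = assign(descriptors, codebook)
        for f, w in zip(frames, words):
            if interval.start <= f < interval.end:
                out[f - interval.start, w] += 1
    sums = out.sum(axis=1, keepdims=True)
    np.divide(out, sums, out=out, where=sums > 0)
    return out


def frame_distance_matrix(
    channels_p: dict[str, np.ndarray],
    channels_q: dict[str, np.ndarray],
    A: dict[str, float] | None = None,
) -> np.ndarray:
    """Matrix d_ij of multichannel frame distances between two intervals.

    ``channels_p[name]`` is the per-frame BoW matrix of channel ``name`` for
    the first interval. Frames with an empty BoW in either interval are
    maximally dissimilar (d = -exp(-1)). With A omitted, every channel gets
    A = 1 (the single-channel form).
    """
    names = sorted(channels_p)
    if sorted(channels_q) != names:
        raise ValueError("channel sets disagree")
    if A is None:
        A = {name: 1.0 for name in names}
    n = len(channels_p[names[0]])
    m = len(channels_q[names[0]])
    empty_p = np.zeros(n, bool)
    empty_q = np.zeros(m, bool)
    for name in names:
        empty_p |= channels_p[name].sum(axis=1) == 0
        empty_q |= channels_q[name].sum(axis=1) == 0
    D = np.empty((n, m))
    for i in range(n):
        if empty_p[i]:
            D[i] = EMPTY_FRAME_DISTANCE
            continue
        expo = np.zeros(m)
        for name in names:
            hi = np.minimum(channels_p[name][i][None, :], channels_q[name]).sum(axis=1)
            expo += (1.0 - hi) / A[name]
        D[i] = -np.exp(-expo)
        D[i, empty_q] = EMPTY_FRAME_DISTANCE
    return D


def candidate_scores(D: np.ndarray, T: int) -> np.ndarray:
    """Scores of the (n-T) x (m-T) aligned subsequence pairs.

    ``scores[i, j]`` is the sum of D over the length-T diagonal starting at
    (i, j), for start offsets 0 .. n-T-1 (the candidate count for intervals
    of n and m frames is (n-T)(m-T)). Intervals of T frames or fewer yield
    no candidates.
    """
    n, m = D.shape
    if n <= T or m <= T:
        return np.empty((0, 0))
    S = np.zeros((n - T, m - T))
    for i in range(n - T):
        for j in range(m - T):
            S[i, j] = np.trace(D[i : i + T, j : j + T])
    return S


def extract_cmps(
    interval_p: Interval,
    interval_q: Interval,
    D: np.ndarray,
    T: int = 10,
    top_k: int = 10,
) -> list[CMP]:
    """Top CMPs between two intervals from their frame-distance matrix.

    All (n-T)(m-T) aligned pairs are scored; the most negative survive, with
    non-overlap suppression: a pair whose (i, j) both lie within T/2 of an
    already selected pair is discarded. Ties are broken by (i, j)
    lexicographic order. Intervals of T frames or fewer give no CMPs.
    """
    S = candidate_scores(D, T)
    if S.size == 0:
        return []
    order = sorted(
        ((S[i, j], i, j) for i in range(S.shape[0]) for j in range(S.shape[1])),
        key=lambda t: (t[0], t[1], t[2]),
    )
    chosen: list[tuple[int, int]] = []
    out: list[CMP] = []
    sup = T // 2
    for score, i, j in order:
        if len(out) >= top_k:
            break
        if any(abs(i - ci) < sup and abs(j - cj) < sup for ci, cj in chosen):
            continue
        chosen.append((i, j))
        out.append(
            CMP(
                interval_p=interval_p,
                start_i=interval_p.start + i,
                interval_q=interval_q,
                start_j=interval_q.start + j,
                T=T,
                score=float(score),
            )
        )
    return out
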