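"""Temporal partitioning of shots into single-behavior intervals.

A shot usually strings together several behaviors (walk, then pause, then
sit). Two motion cues split it: *pauses* — runs of frames with no articulated
motion (sigma below the articulation threshold) — and *periodicity* — gaits
such as walking produce peaks in the frequency domain of the per-frame PoT
bag-of-words signals. Each codeword's occupancy over time is Fourier
transformed, the magnitude spectra are summed over the vocabulary (peaks then
only arise when several codewords recur at the same rate), the DC bin is
dropped and the spectrum normalized to unit total energy. A window is
periodic when its best admissible peak reaches ``theta_H``; the admissible
range requires a period of at least five frames repeating at least three
times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Interval
from .pots import FrameStats, PoT

__all__ = [
    "PartitionConfig",
    "PeriodicityResult",
    "framewise_bow",
    "detect_pauses",
    "periodicity_spectrum",
    "find_periodic_subintervals",
    "partition_shot",
]

MIN_PERIOD = 5
MIN_CYCLES = 3
MIN_WINDOW = MIN_PERIOD * MIN_CYCLES


@dataclass(frozen=True)
class PartitionConfig:
    """Knobs of the partitioning stage.

    ``theta_H`` is the spectral peak threshold (fraction of total non-DC
    energy). Because short windows have few frequency bins, even a flat
    (aperiodic) spectrum concentrates ~1/#bins >= theta_H in its largest bin;
    ``min_peak_ratio`` therefore additionally requires the peak to stand out
    against the median non-DC magnitude, which is scale-free in the window
    length. ``pot_window`` is the PoT length n: a frame's BoW summarizes the
    window [f, f+n), so behavior changes appear in the BoW signal about n/2
    frames early and detected changepoints are shifted accordingly.
    """

    theta_H: float = 0.1  # spectrum peak threshold (energy fraction)
    theta_F: float = 0.1  # articulation threshold used for pause detection
    min_pause: int = 3  # frames
    window_stride: int = 5  # frames, for the sliding-window search
    window_growth: float = 1.5  # geometric window-length ladder
    min_peak_ratio: float = 2.5  # peak vs median non-DC magnitude
    pot_window: int = 10  # PoT length n, for boundary support shift
    merge_period_tol: float = 0.2  # adjacent windows within 20% period merge

    def __post_init__(self):
        if not 0 < self.theta_H < 1:
            raise ValueError("theta_H must be in (0, 1)")
        if self.min_pause < 1 or self.window_stride < 1 or self.window_growth <= 1:
            raise ValueError("invalid partition configuration")


@dataclass
class PeriodicityResult:
    """Best admissible spectral peak of a window."""

    window: Interval
    peak_height: float  # normalized energy fraction in [0, 1]
    period: float  # frames
    frequency: int  # cycles within the window
    peak_ratio: float = float("inf")  # peak vs median non-DC magnitude


def framewise_bow(pots: list[PoT], codebook, frame_count: int) -> np.ndarray:
    """(T, V) matrix of per-frame PoT codeword counts.

    Each PoT contributes to the frame it starts in (the set of PoTs starting
    at f is exactly what the extraction stage produces per frame).
    """
    from .clustering import assign

    V = codebook.centroids.shape[0]
    out = np.zeros((frame_count, V))
    if not pots:
        return out
    words = assign(np.stack([p.descriptor for p in pots]), codebook)
    for p, w in zip(pots, words):
        out[p.start_frame, w] += 1
    return out


def detect_pauses(stats: FrameStats, config: PartitionConfig = PartitionConfig()) -> list[Interval]:
    """Maximal runs of >= min_pause frames with sigma below theta_F."""
    still = stats.sigma < config.theta_F
    pauses = []
    t = 0
    T = len(still)
    while t < T:
        if still[t]:
            start = t
            while t < T and still[t]:
                t += 1
            if t - start >= config.min_pause:
                pauses.append(Interval(shot_id=0, start=start, end=t, label="pause"))
        else:
            t += 1
    return pauses


def periodicity_spectrum(bow: np.ndarray, config: PartitionConfig = PartitionConfig()):
    """Summed FFT magnitude spectrum of the codeword sequences of one window.

    Returns ``(spectrum, result)`` where ``spectrum[k]`` is the normalized
    magnitude at k cycles-per-window (DC excluded, unit total energy) and
    ``result`` is None when the window is too short or carries no energy;
    otherwise the best admissible peak (period >= 5 frames, >= 3 cycles).
    """
    bow = np.asarray(bow, dtype=float)
    L = bow.shape[0]
    if L < MIN_WINDOW:
        raise ValueError(f"window of {L} frames is shorter than {MIN_WINDOW}")
    spec = np.abs(np.fft.rfft(bow, axis=0)).sum(axis=1)
    spec[0] = 0.0  # exclude DC
    total = spec.sum()
    if total <= 0:
        return spec, None
    spec = spec / total
    kmax = int(np.floor(L / MIN_PERIOD))
    admissible = np.arange(len(spec)) >= MIN_CYCLES
    admissible &= np.arange(len(spec)) <= kmax
    if not admissible.any():
        return spec, None
    masked = np.where(admissible, spec, -np.inf)
    k = int(np.argmax(masked))
    median = float(np.median(spec[1:]))
    result = PeriodicityResult(
        window=Interval(shot_id=0, start=0, end=L),
        peak_height=float(spec[k]),
        period=L / k,
        frequency=k,
        peak_ratio=float(spec[k] / median) if median > 0 else float("inf"),
    )
    return spec, result


def _best_window(bow: np.ndarray, start: int, end: int, config: PartitionConfig):
    """Highest-peak sliding window inside [start, end)."""
    seg = end - start
    lengths = []
    L = MIN_WINDOW
    while L < seg:
        lengths.append(L)
        L = int(np.ceil(L * config.window_growth))
    lengths.append(seg)
    best = None
    for L in lengths:
        for s in range(start, end - L + 1, config.window_stride):
            _, res = periodicity_spectrum(bow[s : s + L], config)
            if res is None or res.peak_ratio < config.min_peak_ratio:
                continue
            if best is None or res.peak_height > best.peak_height:
                best = PeriodicityResult(
                    window=Interval(shot_id=0, start=s, end=s + L),
                    peak_height=res.peak_height,
                    period=res.period,
                    frequency=res.frequency,
                    peak_ratio=res.peak_ratio,
                )
    return best


def find_periodic_subintervals(
    interval: Interval,
    bow: np.ndarray,
    config: PartitionConfig = PartitionConfig(),
) -> list[tuple[Interval, PeriodicityResult]]:
    """Greedy recursive extraction of periodic windows from one interval.

    The best-peak sliding window is labeled periodic when its peak reaches
    theta_H; the remaining segments on either side are reprocessed (they may
    hold motion with a different period) until no admissible peak survives.
    Returned windows are disjoint and sorted by start frame.
    """
    found: list[tuple[Interval, PeriodicityResult]] = []

    def recurse(a: int, b: int):
        if b - a < MIN_WINDOW:
            return
        best = _best_window(bow, a, b, config)
        if best is None or best.peak_height < config.theta_H:
            return
        found.append((best.window, best))
        recurse(a, best.window.start)
        recurse(best.window.end, b)

    recurse(interval.start, interval.end)
    found.sort(key=lambda pair: pair[0].start)
    return found


def _l1(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    return v / s if s > 0 else v


def _changepoint_cut(bow: np.ndarray, left: Interval, right: Interval, g0: int, g1: int, config: PartitionConfig) -> int:
    """Best cut inside a gap between two periodic windows.

    Gap frames are compared (histogram intersection) against the mean BoW
    profiles of the two windows; the cut maximizes the agreement of each side
    with its neighbor. Because frame f's BoW covers frames [f, f+n), the BoW
    changepoint leads the behavior change by about n/2 frames; the returned
    cut is shifted accordingly (clamped to the gap).
    """
    if g1 <= g0:
        return g0
    prof_l = _l1(bow[left.start : left.end].sum(axis=0))
    prof_r = _l1(bow[right.start : right.end].sum(axis=0))
    sim_l = np.array([np.minimum(_l1(bow[f]), prof_l).sum() for f in range(g0, g1)])
    sim_r = np.array([np.minimum(_l1(bow[f]), prof_r).sum() for f in range(g0, g1)])
    diff = sim_l - sim_r
    best_score, best_c = -np.inf, g0
    for c in range(g0, g1 + 1):
        score = diff[: c - g0].sum() - diff[c - g0 :].sum()
        if score > best_score:
            best_score, best_c = score, c
    return int(np.clip(best_c + config.pot_window // 2, g0, g1))


def partition_shot(
    frame_count: int,
    bow: np.ndarray,
    stats: FrameStats,
    config: PartitionConfig = PartitionConfig(),
    shot_id: int = 0,
) -> list[Interval]:
    """Partition a shot into single-behavior intervals.

    Pauses are cut first (pause frames carry no articulated motion and are
    dropped from the output); each remaining segment is refined by periodic
    windows. Window boundaries are then reconciled with the segment: gaps
    between two periodic windows are absorbed at a BoW-changepoint cut,
    edge gaps shorter than the minimum analyzable window extend the adjacent
    window, longer edge gaps stay as their own (aperiodic) interval, and
    adjacent windows with near-identical periods merge. Every non-pause
    frame belongs to exactly one output interval.
    """
    pauses = detect_pauses(stats, config)
    cuts = [0]
    for p in pauses:
        cuts.extend([p.start, p.end])
    cuts.append(frame_count)
    segments = [(a, b) for a, b in zip(cuts[::2], cuts[1::2]) if b - a >= 2]

    out: list[Interval] = []
    for a, b in segments:
        periodic = find_periodic_subintervals(Interval(shot_id, a, b), bow, config)
        if not periodic:
            out.append(Interval(shot_id, a, b))
            continue
        # merge adjacent windows whose periods agree within tolerance
        merged: list[tuple[list[int], PeriodicityResult]] = []
        for w, res in periodic:
            if merged:
                (ps, pe), pres = merged[-1]
                close = abs(res.period - pres.period) <= config.merge_period_tol * max(res.period, pres.period)
                if close and w.start - pe < MIN_WINDOW:
                    merged[-1] = ([ps, w.end], pres)
                    continue
            merged.append(([w.start, w.end], res))
        # resolve gaps
        pieces: list[list[int]] = []
        cursor = a
        for idx, ((ws, we), res) in enumerate(merged):
            gap = ws - cursor
            if gap > 0:
                if cursor == a:  # edge gap
                    if gap < MIN_WINDOW:
                        ws = cursor
                    else:
                        pieces.append([cursor, ws])
                else:  # middle gap: changepoint between the two windows
                    left = Interval(shot_id, *map(int, pieces[-1]))
                    cut = _changepoint_cut(bow, left, Interval(shot_id, ws, we), cursor, ws, config)
                    pieces[-1][1] = cut
                    ws = cut
            pieces.append([ws, we])
            cursor = we
        tail = b - cursor
        if tail > 0:
            if tail < MIN_WINDOW:
                pieces[-1][1] = b
            else:
                pieces.append([cursor, b])
        out.extend(Interval(shot_id, int(s), int(e)) for s, e in pieces if e - s >= 2)
    return out
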