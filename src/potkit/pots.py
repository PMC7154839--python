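"""Pair-of-trajectories (PoT) extraction.

A PoT is an *ordered* pair of dense point trajectories tracked over ``n``
consecutive frames: the motion of the second trajectory (the *swing*) is
measured in the local coordinate frame of the first (the *anchor*). Pairs are
preferentially selected across joints of the articulated object — the anchor
moving close to the object's median velocity, the swing deviating from it —
which makes the descriptor capture the relative motion of body parts (knee vs
paw, torso vs head) rather than the dominant translation.

The descriptor of a PoT starting at frame f is

    P = (theta, d^2/D, ..., d^n/D),

where r^k is the anchor-to-swing vector in frame k, d^k = r^k - r^{k-1} the
relative displacement, D = sum_k ||d^k|| the total relative displacement, and
theta the angle of r^1. Recording only the angle of the initial offset keeps
the descriptor scale invariant; differencing the r^k makes it invariant to
camera panning. Dimensionality is 2(n-1)+1; n = 10 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Shot, Trajectory

__all__ = [
    "PoTConfig",
    "FrameStats",
    "PoT",
    "frame_stats",
    "score_candidates",
    "select_pots",
    "pot_descriptor",
    "extract_pots",
]


@dataclass(frozen=True)
class PoTConfig:
    """Knobs of the PoT stage.

    n — PoT length in frames; theta_F — articulation threshold below which a
    frame is pruned (no PoTs start there); theta_P — fraction of candidate
    pairs retained per frame.
    """

    n: int = 10
    theta_F: float = 0.1
    theta_P: float = 0.15

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("PoT length n must be >= 2")
        if not 0 < self.theta_P <= 1:
            raise ValueError("theta_P must be in (0, 1]")
        if self.theta_F < 0:
            raise ValueError("theta_F must be >= 0")


@dataclass
class FrameStats:
    """Per-frame foreground motion statistics.

    ``median_velocity[f]`` is the per-axis median optical-flow displacement
    over mask pixels (the object's translation estimate); ``sigma[f]`` is the
    standard deviation of the flow magnitudes over mask pixels divided by
    their mean (a unitless articulation measure, 0 for rigid motion);
    ``articulation[f]`` is s(f), the mean of sigma over the PoT window
    [f, f+n-1]. ``pruned[f]`` marks frames where no PoT may start, either
    because s(f) < theta_F or because the window has an empty mask or runs
    past the shot.
    """

    median_velocity: np.ndarray  # (T, 2)
    sigma: np.ndarray  # (T,)
    articulation: np.ndarray  # (T,) s(f); NaN where undefined
    pruned: np.ndarray  # (T,) bool


def frame_stats(flow: np.ndarray, masks: np.ndarray, config: PoTConfig = PoTConfig()) -> FrameStats:
    """Compute per-frame flow statistics and the frame-pruning flags.

    ``flow`` has one entry per frame transition (T-1 of them); statistics for
    the final frame reuse the last transition, mirroring how per-trajectory
    velocities are formed.
    """
    T = masks.shape[0]
    if flow.shape[0] != T - 1:
        raise ValueError("expected flow with one entry per frame transition")
    n = config.n
    median_velocity = np.zeros((T, 2))
    sigma = np.zeros(T)
    empty = np.zeros(T, dtype=bool)
    for t in range(T - 1):
        fg = masks[t]
        if not fg.any():
            empty[t] = True
            continue
        v = flow[t][fg]  # (N, 2)
        median_velocity[t] = np.median(v, axis=0)
        mag = np.linalg.norm(v, axis=1)
        mean = mag.mean()
        sigma[t] = mag.std() / mean if mean > 1e-6 else 0.0
    # last frame has no outgoing flow: reuse the previous transition
    median_velocity[T - 1] = median_velocity[T - 2]
    sigma[T - 1] = sigma[T - 2]
    empty[T - 1] = empty[T - 2]

    articulation = np.full(T, np.nan)
    pruned = np.ones(T, dtype=bool)
    for f in range(T - n + 1):
        if empty[f : f + n].any():
            continue
        articulation[f] = sigma[f : f + n].mean()
        pruned[f] = articulation[f] < config.theta_F
    return FrameStats(median_velocity, sigma, articulation, pruned)


def _window_velocities(traj: Trajectory, f: int, n: int) -> np.ndarray:
    """Per-frame velocities of a trajectory over [f, f+n-1].

    The velocity at frame k is point(k+1) - point(k); the final frame of the
    window reuses the last available displacement (a window's last frame may
    be the trajectory's last).
    """
    i0 = f - traj.start_frame
    pts = traj.points[i0 : i0 + n]
    disp = np.diff(pts, axis=0)
    if traj.end_frame > f + n:  # a real next point exists
        nxt = traj.points[i0 + n] - pts[-1]
        return np.vstack([disp, nxt[None]])
    return np.vstack([disp, disp[-1][None]])


def score_candidates(
    trajectories: list[Trajectory],
    stats: FrameStats,
    f: int,
    config: PoTConfig = PoTConfig(),
) -> list[tuple[float, int, int]]:
    """Score all ordered candidate pairs starting at frame f.

    The score of an ordered pair (anchor a, swing s) is

        S = sum_k ||v_s^k - v_m^k|| - ||v_a^k - v_m^k||,

    summed over the n window frames, where v_m is the median foreground
    velocity. Large S means the swing deviates from the object's translation
    while the anchor follows it. Both orderings of every unordered pair are
    scored (S is antisymmetric). Returns ``(score, anchor_id, swing_id)``
    tuples, unsorted.
    """
    n = config.n
    live = [t for t in trajectories if t.alive(f, f + n)]
    if len(live) < 2:
        return []
    vm = stats.median_velocity[f : f + n]  # (n, 2)
    dev = np.array([np.linalg.norm(_window_velocities(t, f, n) - vm, axis=1).sum() for t in live])
    ids = [t.id for t in live]
    out = []
    for i in range(len(live)):
        for j in range(len(live)):
            if i != j:
                out.append((float(dev[j] - dev[i]), ids[i], ids[j]))
    return out


def select_pots(
    scored_pairs: list[tuple[float, int, int]],
    config: PoTConfig = PoTConfig(),
) -> list[tuple[float, int, int]]:
    """Keep the ceil(theta_P * N) highest-scoring ordered pairs.

    Ties at the cutoff are broken by (anchor_id, swing_id) lexicographic
    order, so selection is deterministic.
    """
    if not scored_pairs:
        return []
    keep = int(np.ceil(config.theta_P * len(scored_pairs)))
    ranked = sorted(scored_pairs, key=lambda p: (-p[0], p[1], p[2]))
    return ranked[:keep]


@dataclass
class PoT:
    """An ordered anchor/swing pair with its descriptor."""

    anchor_id: int
    swing_id: int
    start_frame: int
    descriptor: np.ndarray = field(repr=False)  # length 2(n-1)+1


def pot_descriptor(
    anchor: Trajectory,
    swing: Trajectory,
    start_frame: int,
    config: PoTConfig = PoTConfig(),
) -> np.ndarray | None:
    """Descriptor (theta, d^2/D, ..., d^n/D) of one ordered pair.

    Returns None when the pair is rigid over the window (D = 0): such pairs
    carry no relative motion and are discarded rather than emitted with a
    zero vector.
    """
    n = config.n
    for t in (anchor, swing):
        if not t.alive(start_frame, start_frame + n):
            raise ValueError("trajectory does not cover the PoT window")
    ia = start_frame - anchor.start_frame
    isw = start_frame - swing.start_frame
    r = swing.points[isw : isw + n] - anchor.points[ia : ia + n]  # (n, 2)
    d = np.diff(r, axis=0)  # (n-1, 2)
    D = np.linalg.norm(d, axis=1).sum()
    if D == 0:
        return None
    theta = np.arctan2(r[0, 1], r[0, 0])
    if theta == -np.pi:  # keep theta in (-pi, pi]
        theta = np.pi
    return np.concatenate([[theta], (d / D).ravel()])


def _foreground_trajectories(shot: Shot) -> list[Trajectory]:
    """Trajectories whose every point lies on the foreground mask.

    A trajectory with any point off the mask in any frame of its span is
    treated as background and removed (strict rule).
    """
    H, W = shot.masks.shape[1:]
    keep = []
    for tr in shot.trajectories:
        xs = np.clip(np.round(tr.points[:, 0]).astype(int), 0, W - 1)
        ys = np.clip(np.round(tr.points[:, 1]).astype(int), 0, H - 1)
        frames = np.arange(tr.start_frame, tr.end_frame)
        if shot.masks[frames, ys, xs].all():
            keep.append(tr)
    return keep


def extract_pots(shot: Shot, config: PoTConfig = PoTConfig()) -> list[PoT]:
    """Full PoT extraction for one shot.

    Background trajectories are removed first; frames with s(f) < theta_F
    yield no PoTs; elsewhere candidate ordered pairs are scored, the top
    theta_P fraction selected per frame, and descriptors computed (rigid
    pairs dropped). Windows start at every non-pruned frame, so overlapping
    PoTs from the same pair are allowed.
    """
    if shot.masks is None or shot.flow is None:
        raise ValueError("PoT extraction requires both masks and flow")
    n = config.n
    stats = frame_stats(shot.flow, shot.masks, config)
    fg = _foreground_trajectories(shot)
    pots: list[PoT] = []
    for f in range(shot.frame_count - n + 1):
        if stats.pruned[f]:
            continue
        live = [t for t in fg if t.alive(f, f + n)]
        M = len(live)
        if M < 2:
            continue
        # vectorized equivalent of score_candidates + select_pots +
        # pot_descriptor; per-term arithmetic matches those functions exactly
        vm = stats.median_velocity[f : f + n]
        dev = np.array([np.linalg.norm(_window_velocities(t, f, n) - vm, axis=1).sum() for t in live])
        ids = np.array([t.id for t in live])
        ii, jj = np.nonzero(~np.eye(M, dtype=bool))
        S = dev[jj] - dev[ii]
        keep = int(np.ceil(config.theta_P * len(S)))
        order = np.lexsort((ids[jj], ids[ii], -S))[:keep]
        ai, si = ii[order], jj[order]
        windows = np.stack([t.points[f - t.start_frame : f - t.start_frame + n] for t in live])
        r = windows[si] - windows[ai]  # (K, n, 2)
        d = np.diff(r, axis=1)
        D = np.linalg.norm(d, axis=2).sum(axis=1)
        nz = D > 0  # rigid pairs are discarded
        theta = np.arctan2(r[nz, 0, 1], r[nz, 0, 0])
        theta[theta == -np.pi] = np.pi
        descs = np.concatenate([theta[:, None], (d[nz] / D[nz, None, None]).reshape(nz.sum(), -1)], axis=1)
        for k, (a, s) in enumerate(zip(ids[ai[nz]], ids[si[nz]])):
            pots.append(PoT(int(a), int(s), f, descs[k]))
    return pots


def descriptor_matrix(pots: list[PoT]) -> np.ndarray:
    """Stack PoT descriptors into an (N, 2(n-1)+1) matrix."""
    if not pots:
        return np.empty((0, 0))
    return np.stack([p.descriptor for p in pots])
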