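"""Non-rigid alignment with thin-plate splines (TPS), robust point matching
(TPS-RPM) and the time-varying extension (TTPS).

A TPS is an affine transform plus a radial-basis warp minimizing the
integrated squared second derivatives (bending energy); fitting point pairs
under a smoothness weight ``lambda`` has a closed-form solution. When the
correspondences are unknown, TPS-RPM alternates a softassign estimate of a
continuous correspondence matrix M with TPS refits, inside a deterministic
annealing loop: the temperature controls the fuzziness of M (and, tied to
it, the smoothness weight), so early iterations see a nearly rigid, global
problem and late iterations a sharp, local one. Outlier rows/columns absorb
points without a counterpart.

TTPS aligns two T-frame sequences with one TPS per frame while forcing all
frames to share a single correspondence matrix: edge points extracted at an
anchor frame tau are advected to every other frame with optical flow, so a
correspondence established at tau stays a correspondence everywhere. One
candidate is built per choice of tau and the minimum-energy candidate wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mappings import Homography, bilinear_sample

__all__ = [
    "TPSMapping",
    "TPSRPMConfig",
    "EdgePointSet",
    "TTPSAlignment",
    "tps_kernel",
    "fit_tps",
    "tps_rpm",
    "extract_foreground_edges",
    "propagate_edges",
    "fit_ttps",
    "apply_mapping",
]


def tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, written on squared distances (U(0) = 0)."""
    out = np.zeros_like(r2, dtype=float)
    nz = r2 > 0
    out[nz] = 0.5 * r2[nz] * np.log(r2[nz])
    return out


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


@dataclass
class TPSMapping:
    """f(v) = d [1 v] + sum_j w_j U(|v - c_j|), fit control points c."""

    control_points: np.ndarray  # (N, 2)
    warp_coefficients: np.ndarray  # (N, 2)
    affine: np.ndarray  # (3, 2); rows bias, x, y
    smoothness: float  # lambda used at fit time
    bending_energy: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        K = tps_kernel(_sq_dists(pts, self.control_points))
        P = np.hstack([np.ones((len(pts), 1)), pts])
        return P @ self.affine + K @ self.warp_coefficients

    def numeric_inverse(self, image_size: tuple[int, int], grid_step: int = 8) -> "TPSMapping":
        """Approximate inverse, fit on the images of a regular grid."""
        H, W = image_size
        gy, gx = np.mgrid[0:H:grid_step, 0:W:grid_step]
        grid = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(float)
        fwd = self.apply(grid)
        return fit_tps(grid, fwd, lam=1e-6)


@dataclass
class ComposedMapping:
    """``second`` applied after ``first`` (used for homography-initialized TPS)."""

    first: object
    second: TPSMapping

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.second.apply(self.first.apply(points))

    @property
    def bending_energy(self) -> float:
        return self.second.bending_energy


def fit_tps(
    targets: np.ndarray,
    control_points: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
) -> TPSMapping:
    """Closed-form TPS fit: minimize sum_i w_i |u_i - f(v_i)|^2 + lam * bending.

    ``targets`` u_i correspond one-to-one to ``control_points`` v_i. Weights
    (e.g. correspondence mass from a softassign matrix) default to 1. For
    lam -> 0 the fit interpolates; for lam -> inf it collapses to the
    weighted least-squares affine fit. A numerically singular system falls
    back to a ridge-regularized solve with a warning.
    """
    V = np.atleast_2d(np.asarray(control_points, float))
    U = np.atleast_2d(np.asarray(targets, float))
    if len(V) < 3:
        raise ValueError("TPS needs at least 3 control points")
    if V.shape != U.shape:
        raise ValueError("targets and control points must align one-to-one")
    n = len(V)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = np.maximum(w, 1e-12)
    K = tps_kernel(_sq_dists(V, V))
    P = np.hstack([np.ones((n, 1)), V])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K + lam * np.diag(1.0 / w)
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = U
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("singular TPS system; using ridge-regularized solve", stacklevel=2)
        sol = np.linalg.solve(A + 1e-8 * np.eye(n + 3), rhs)
    Wc = sol[:n]
    d = sol[n:]
    bending = float(np.einsum("ia,ij,ja->", Wc, K, Wc))
    return TPSMapping(V.copy(), Wc, d, smoothness=lam, bending_energy=bending)


# ---------------------------------------------------------------------------
# TPS-RPM


@dataclass(frozen=True)
class TPSRPMConfig:
    """Deterministic-annealing schedule and softassign knobs.

    ``initial_temp=None`` starts at the mean squared nearest-neighbor
    distance; temperature multiplies by ``anneal_rate`` until ``final_temp``
    (px^2). ``lambda0`` scales the smoothness weight, tied to the
    temperature (lam = lambda0 * T). ``outlier_k``: points farther than
    about outlier_k * sqrt(T) from every counterpart drain into the outlier
    bin.
    """

    initial_temp: float | None = None
    final_temp: float = 1.0
    anneal_rate: float = 0.93
    inner_iterations: int = 5
    sinkhorn_iterations: int = 10
    lambda0: float = 1.0
    outlier_k: float = 2.0
    max_inner_no_progress: int = 5


def _softassign(D2: np.ndarray, temp: float, config: TPSRPMConfig) -> np.ndarray:
    """Doubly-normalized soft correspondence matrix with outlier bins."""
    n1, n2 = D2.shape
    M = np.empty((n1 + 1, n2 + 1))
    M[:n1, :n2] = np.exp(-D2 / (2.0 * temp))
    M[n1, :] = np.exp(-0.5 * config.outlier_k**2)
    M[:, n2] = np.exp(-0.5 * config.outlier_k**2)
    for _ in range(config.sinkhorn_iterations):
        M[:n1] /= M[:n1].sum(axis=1, keepdims=True)
        M[:, :n2] /= M[:, :n2].sum(axis=0, keepdims=True)
    return M[:n1, :n2]


def _correspondence_targets(M: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-V-point target positions and masses from the soft matrix."""
    mass = M.sum(axis=0)
    safe = np.maximum(mass, 1e-12)
    Y = (M.T @ U) / safe[:, None]
    return Y, mass


def _rpm_energy(M: np.ndarray, D2: np.ndarray, lam: float, bending: float) -> float:
    return float((M * D2).sum() + lam * bending)


def _rpm_free_energy(M: np.ndarray, D2: np.ndarray, lam: float, bending: float, temp: float) -> float:
    """Annealed objective: correspondence energy plus the temperature-scaled
    entropy barrier that the softassign M-update actually minimizes."""
    m = np.clip(M, 1e-300, None)
    return _rpm_energy(M, D2, lam, bending) + 2.0 * temp * float((m * np.log(m)).sum())


def rpm_fixed_temperature_energies(
    U: np.ndarray,
    V: np.ndarray,
    temp: float,
    iterations: int = 10,
    config: TPSRPMConfig = TPSRPMConfig(),
    sinkhorn_iterations: int = 200,
) -> list[float]:
    """Annealed-objective trace of the alternation at one fixed temperature.

    The softassign M-update minimizes, subject to the (augmented) row/column
    normalization, the free energy

        F = 1/2 sum m_ij D2_ij + 1/2 T k^2 (outlier mass)
            + T sum m log m + 1/2 lam ||L(f)||,

    and the TPS refit minimizes the same F over f at fixed M, so each full
    alternation is a descent step on F once the Sinkhorn scaling has
    converged. Returns F after every alternation (used by tests asserting
    monotone descent).
    """
    U = np.atleast_2d(np.asarray(U, float))
    V = np.atleast_2d(np.asarray(V, float))
    cfg = TPSRPMConfig(
        initial_temp=config.initial_temp,
        final_temp=config.final_temp,
        anneal_rate=config.anneal_rate,
        inner_iterations=config.inner_iterations,
        sinkhorn_iterations=sinkhorn_iterations,
        lambda0=config.lambda0,
        outlier_k=config.outlier_k,
    )
    lam = max(cfg.lambda0 * temp, 1e-8)
    f = fit_tps(V, V, lam=lam)
    energies = []
    n1, n2 = len(U), len(V)
    for _ in range(iterations):
        D2 = _sq_dists(U, f.apply(V))
        Maug = np.empty((n1 + 1, n2 + 1))
        Maug[:n1, :n2] = np.exp(-D2 / (2.0 * temp))
        Maug[n1, :] = np.exp(-0.5 * cfg.outlier_k**2)
        Maug[:, n2] = np.exp(-0.5 * cfg.outlier_k**2)
        for _s in range(cfg.sinkhorn_iterations):
            Maug[:n1] /= Maug[:n1].sum(axis=1, keepdims=True)
            Maug[:, :n2] /= Maug[:, :n2].sum(axis=0, keepdims=True)
        M = Maug[:n1, :n2]
        Y, mass = _correspondence_targets(M, U)
        f = fit_tps(Y, V, lam=lam, weights=mass)
        D2 = _sq_dists(U, f.apply(V))
        outlier_mass = Maug[n1, :n2].sum() + Maug[:n1, n2].sum()
        m = np.clip(Maug, 1e-300, None)
        F = (
            0.5 * float((M * D2).sum())
            + 0.5 * temp * cfg.outlier_k**2 * float(outlier_mass)
            + temp * float((m * np.log(m)).sum())
            + 0.5 * lam * f.bending_energy
        )
        energies.append(F)
    return energies


def tps_rpm(
    U: np.ndarray,
    V: np.ndarray,
    init_mapping=None,
    config: TPSRPMConfig = TPSRPMConfig(),
) -> tuple[TPSMapping | ComposedMapping, np.ndarray, dict]:
    """Jointly estimate a TPS f (with u ~ f(v)) and soft correspondences M.

    ``init_mapping`` (e.g. a homography from the coarse alignment stage) is
    applied to V up front and composed into the returned mapping. Returns
    ``(mapping, M, info)``; ``info`` holds the per-alternation energy trace
    grouped by temperature and a convergence flag.
    """
    U = np.atleast_2d(np.asarray(U, float))
    V0 = np.atleast_2d(np.asarray(V, float))
    if len(U) == 0 or len(V0) == 0:
        raise ValueError("point sets must be nonempty")
    Vw = init_mapping.apply(V0) if init_mapping is not None else V0.copy()

    if config.initial_temp is None:
        d2 = _sq_dists(U, Vw)
        temp = float(0.5 * (d2.min(axis=1).mean() + d2.min(axis=0).mean()))
        temp = max(temp, config.final_temp * 2)
    else:
        temp = config.initial_temp

    f = fit_tps(Vw, Vw, lam=max(config.lambda0 * temp, 1e-8))  # identity start
    M = None
    energy_trace: list[tuple[float, float, float]] = []  # (temperature, energy, free energy)
    converged = True
    while temp >= config.final_temp:
        lam = max(config.lambda0 * temp, 1e-8)
        prev = np.inf
        for _ in range(config.inner_iterations):
            fV = f.apply(Vw)
            D2 = _sq_dists(U, fV)
            M = _softassign(D2, temp, config)
            Y, mass = _correspondence_targets(M, U)
            f = fit_tps(Y, Vw, lam=lam, weights=mass)
            D2_new = _sq_dists(U, f.apply(Vw))
            e = _rpm_energy(M, D2_new, lam, f.bending_energy)
            fe = _rpm_free_energy(M, D2_new, lam, f.bending_energy, temp)
            energy_trace.append((temp, e, fe))
            if abs(prev - e) < 1e-9 * (1 + abs(e)):
                break
            prev = e
        temp *= config.anneal_rate

    info = {"energy_trace": energy_trace, "converged": converged, "final_temp": temp / config.anneal_rate}
    mapping = f if init_mapping is None else ComposedMapping(init_mapping, f)
    return mapping, M, info


# ---------------------------------------------------------------------------
# foreground edges


@dataclass
class EdgePointSet:
    """Edge points of one frame, with strength and provenance.

    ``source_frame`` records where the points were extracted; after flow
    propagation the index identity is preserved (point i of the propagated
    set is point i of the source set).
    """

    points: np.ndarray  # (N, 2)
    strengths: np.ndarray  # (N,)
    frame: int
    source_frame: int | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.strengths = np.asarray(self.strengths, float)
        if self.source_frame is None:
            self.source_frame = self.frame


def gradient_edge_strength(image: np.ndarray) -> np.ndarray:
    """Default edge provider: Sobel gradient magnitude normalized to [0, 1]."""
    img = np.asarray(image, float)
    gx = ndimage.sobel(img, axis=1)
    gy = ndimage.sobel(img, axis=0)
    mag = np.hypot(gx, gy)
    peak = mag.max()
    return mag / peak if peak > 0 else mag


def extract_foreground_edges(
    edge_strength: np.ndarray,
    mask: np.ndarray,
    frame: int = 0,
    max_points: int = 1000,
    prune_below: float = 0.2,
    seed: int = 0,
) -> EdgePointSet:
    """Score edges by strength x foreground proximity; prune and subsample.

    The edge strength (in [0, 1]; any pluggable detector) is multiplied by a
    weight derived from the distance transform to the foreground mask,
    exp(-dist / (0.1 * bbox diagonal)), so on-mask points keep their strength
    and clutter far from the object decays to zero on a scale-free ramp.
    Points scoring <= ``prune_below`` are dropped, the rest uniformly
    subsampled to ``max_points`` (seeded).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty foreground mask")
    strength = np.asarray(edge_strength, float)
    if strength.shape != mask.shape:
        raise ValueError("edge strength and mask dimensions disagree")
    dist = ndimage.distance_transform_edt(~mask)
    ys, xs = np.nonzero(mask)
    diag = float(np.hypot(xs.max() - xs.min(), ys.max() - ys.min()))
    weight = np.exp(-dist / max(0.1 * diag, 1e-9))
    score = strength * weight
    keep = score > prune_below
    ys, xs = np.nonzero(keep)
    pts = np.stack([xs, ys], axis=1).astype(float)
    sc = score[ys, xs]
    if len(pts) > max_points:
        idx = np.random.default_rng(seed).choice(len(pts), size=max_points, replace=False)
        idx.sort()
        pts, sc = pts[idx], sc[idx]
    return EdgePointSet(points=pts, strengths=sc, frame=frame)


def _advect(points: np.ndarray, flow: np.ndarray, from_t: int, to_t: int) -> tuple[np.ndarray, np.ndarray]:
    """Advect points frame-by-frame; returns (positions, alive mask).

    Backward propagation inverts the forward flow by fixed-point iteration
    (the source p of a destination q satisfies p = q - flow(p)), keeping the
    best-residual iterate. Points whose inversion does not converge — e.g.
    at motion discontinuities, where no consistent pre-image exists — are
    retired, like points leaving the image.
    """
    H, W = flow.shape[1:3]
    pts = points.copy()
    alive = np.ones(len(pts), dtype=bool)
    step = 1 if to_t >= from_t else -1
    for t in range(from_t, to_t, step):
        if step == 1:
            pts[alive] += bilinear_sample(flow[t], pts[alive])
        else:
            q = pts[alive]
            p = q - bilinear_sample(flow[t - 1], q)
            best_p = p.copy()
            best_r = np.linalg.norm(p + bilinear_sample(flow[t - 1], p) - q, axis=1)
            for _ in range(7):
                p = q - bilinear_sample(flow[t - 1], p)
                r = np.linalg.norm(p + bilinear_sample(flow[t - 1], p) - q, axis=1)
                better = r < best_r
                best_p[better] = p[better]
                best_r[better] = r[better]
            ok = best_r <= 0.5
            sub = alive.copy()
            sub[alive] = ok
            pts[alive] = best_p
            alive = sub
        inside = (pts[:, 0] >= 0) & (pts[:, 0] <= W - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= H - 1)
        alive &= inside
    return pts, alive


def propagate_edges(edges: EdgePointSet, flow: np.ndarray, from_t: int, to_t: int) -> EdgePointSet:
    """Advect an edge set to another frame; points leaving the image retire.

    Index identity is preserved for surviving points (the returned set keeps
    the source ordering restricted to the alive subset — use
    :func:`propagate_track` when all frames must stay index-aligned).
    """
    pts, alive = _advect(edges.points, flow, from_t, to_t)
    return EdgePointSet(
        points=pts[alive],
        strengths=edges.strengths[alive],
        frame=to_t,
        source_frame=edges.source_frame,
    )


def propagate_track(edges: EdgePointSet, flow: np.ndarray, frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions of every edge point in every frame of a T-frame window.

    Returns ``(track, alive)`` with track (T, N, 2); ``alive[i]`` is True only
    if point i stays inside the image in all frames (retired otherwise).
    """
    T = frames
    N = len(edges.points)
    track = np.zeros((T, N, 2))
    alive = np.ones(N, dtype=bool)
    track[edges.frame] = edges.points
    for t in range(edges.frame + 1, T):
        pts, ok = _advect(track[t - 1], flow, t - 1, t)
        track[t] = pts
        alive &= ok
    for t in range(edges.frame - 1, -1, -1):
        pts, ok = _advect(track[t + 1], flow, t + 1, t)
        track[t] = pts
        alive &= ok
    return track, alive


# ---------------------------------------------------------------------------
# temporal TPS


@dataclass
class TTPSAlignment:
    """Per-frame TPS mappings sharing one correspondence matrix.

    ``mappings[t]`` maps sequence-2 coordinates of frame t into sequence 1
    (u = f^t(v)); ``correspondence`` is the soft matrix M estimated at the
    anchor frame and reused, by flow propagation, in every frame.
    """

    mappings: list  # T mappings (TPSMapping or ComposedMapping)
    correspondence: np.ndarray  # (N1, N2) soft matrix
    anchor_frame: int
    energy: float
    per_frame_energy: list[float] = field(default_factory=list)
    candidate_energies: list[float] = field(default_factory=list)


def fit_ttps(
    edges1: list[EdgePointSet],
    edges2: list[EdgePointSet],
    flow1: np.ndarray,
    flow2: np.ndarray,
    init_homography: Homography | None = None,
    config: TPSRPMConfig = TPSRPMConfig(),
    anchor_frames: list[int] | None = None,
) -> TTPSAlignment:
    """Time-varying TPS over a T-frame CMP, one candidate per anchor frame.

    For each anchor tau: TPS-RPM aligns the frame-tau edge sets (sequence 2
    onto sequence 1), its correspondence matrix is frozen, both edge sets are
    flow-advected to every other frame, and the remaining per-frame TPSs are
    fit to the propagated pairs under the frozen correspondences — so the
    shared-correspondence constraint holds by construction. The candidate
    with the lowest total energy (matched-pair residual plus bending, summed
    over frames) is returned. Frames with fewer than 3 usable points skip
    the candidate; if every candidate is skipped a ValueError is raised.
    """
    T = len(edges1)
    if len(edges2) != T:
        raise ValueError("edge set lists must cover the same T frames")
    taus = anchor_frames if anchor_frames is not None else list(range(T))
    lam = max(config.lambda0 * config.final_temp, 1e-8)

    best: TTPSAlignment | None = None
    candidate_energies: list[float] = []
    for tau in taus:
        track1, alive1 = propagate_track(edges1[tau], flow1, T)
        track2, alive2 = propagate_track(edges2[tau], flow2, T)
        U_all = track1[:, alive1]
        V_all = track2[:, alive2]
        if U_all.shape[1] < 3 or V_all.shape[1] < 3:
            candidate_energies.append(np.inf)
            continue
        _, M, _ = tps_rpm(U_all[tau], V_all[tau], init_mapping=init_homography, config=config)
        # freeze hard correspondences: each control point v_j pairs with its
        # best u, carrying the soft weight. A soft M would mix u points that
        # are close at the anchor frame but diverge under motion when
        # propagated to the other frames.
        i_star = np.argmax(M, axis=0)
        w_j = M[i_star, np.arange(M.shape[1])]
        keep_j = w_j > 0.05
        if keep_j.sum() < 3:
            candidate_energies.append(np.inf)
            continue
        i_star, w_hard = i_star[keep_j], w_j[keep_j]
        mappings: list = [None] * T
        per_frame: list[float] = [0.0] * T
        ok = True
        for t in range(T):
            Vt_all = init_homography.apply(V_all[t]) if init_homography is not None else V_all[t]
            Vt = Vt_all[keep_j]
            Yt = U_all[t][i_star]
            if len(Vt) < 3:
                ok = False
                break
            f_t = fit_tps(Yt, Vt, lam=lam, weights=w_hard)
            resid = np.sum(w_hard * np.sum((Yt - f_t.apply(Vt)) ** 2, axis=1))
            per_frame[t] = float(resid + lam * f_t.bending_energy)
            mappings[t] = f_t if init_homography is None else ComposedMapping(init_homography, f_t)
        if not ok:
            candidate_energies.append(np.inf)
            continue
        energy = float(sum(per_frame))
        candidate_energies.append(energy)
        if best is None or energy < best.energy:
            best = TTPSAlignment(
                mappings=mappings,
                correspondence=M,
                anchor_frame=tau,
                energy=energy,
                per_frame_energy=per_frame,
            )
    if best is None:
        raise ValueError("every TTPS candidate was skipped (too few usable points)")
    best.candidate_energies = candidate_energies
    return best


# ---------------------------------------------------------------------------
# applying alignments


def apply_mapping(alignment, points: np.ndarray, frame_t: int = 0, direction: str = "forward", image_size: tuple[int, int] | None = None) -> np.ndarray:
    """Map points through an alignment, u = f(v) convention.

    ``forward`` sends sequence-2 coordinates into sequence 1; ``reverse``
    uses the inverse (exact for homographies, numeric for TPS — fit to the
    swapped images of a grid over ``image_size``, which defaults to the
    bounding square of the points).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")

    from .homography import HomographyAlignment  # local import to avoid cycle

    if isinstance(alignment, HomographyAlignment):
        H = alignment.homography if direction == "forward" else alignment.homography.inverse()
        return H.apply(pts)
    if isinstance(alignment, TTPSAlignment):
        f = alignment.mappings[frame_t]
        if direction == "forward":
            return f.apply(pts)
        if image_size is None:
            hi = int(np.ceil(pts.max())) + 64
            image_size = (hi, hi)
        return _numeric_inverse_of(f, image_size).apply(pts)
    # bare mapping objects (Homography, TPSMapping, ComposedMapping)
    if direction == "forward":
        return alignment.apply(pts)
    if hasattr(alignment, "inverse"):
        return alignment.inverse().apply(pts)
    if image_size is None:
        hi = int(np.ceil(pts.max())) + 64
        image_size = (hi, hi)
    return _numeric_inverse_of(alignment, image_size).apply(pts)


def _numeric_inverse_of(mapping, image_size: tuple[int, int]) -> TPSMapping:
    H, W = image_size
    gy, gx = np.mgrid[0:H:8, 0:W:8]
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(float)
    fwd = mapping.apply(grid)
    return fit_tps(grid, fwd, lam=1e-6)
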