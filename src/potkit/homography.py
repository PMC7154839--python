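"""Coarse global alignment of a CMP with a single homography.

Trajectories spanning the two T-frame sequences are matched by a modified
trajectory-shape descriptor — the concatenated frame-to-frame displacements
plus the scale-normalized offset from the trajectory to the foreground center
of mass, which disambiguates trajectories with identical shape (e.g. all
points on a rigidly translating torso). A homography is then fit by RANSAC
over the matches, in one of two modes:

* IM (independent matching) treats every point correspondence independently;
* TM (temporal matching) samples whole trajectory matches (4 per iteration,
  solving the 4T-point least-squares system), and calls a match an outlier
  only when more than half of its point correspondences are outliers — which
  enforces geometric consistency over the whole CMP.

Optionally the per-frame foreground bounding-box corner correspondences are
added to every least-squares fit as a regularizer: trajectory matches often
cover only one body region, and the (coarse) boxes anchor the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Trajectory
from .mappings import Homography

__all__ = [
    "TrajectoryMatch",
    "HomographyAlignment",
    "foreground_boxes",
    "modified_ts_descriptor",
    "match_trajectories",
    "fit_homography",
]


@dataclass
class TrajectoryMatch:
    """One trajectory in sequence 1 matched to one in sequence 2.

    ``points1``/``points2`` hold the T per-frame point correspondences.
    """

    id1: int
    id2: int
    distance: float
    points1: np.ndarray  # (T, 2)
    points2: np.ndarray  # (T, 2)


@dataclass
class HomographyAlignment:
    """RANSAC result: H maps sequence-2 coordinates into sequence 1 (u = H v)."""

    homography: Homography
    mode: str  # "im" | "tm"
    inlier_matches: list[int] = field(default_factory=list)  # indices into the match list
    outlier_fraction: float = 0.0
    fg_regularized: bool = False


def mask_center_of_mass(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty foreground mask")
    return np.array([xs.mean(), ys.mean()])


def mask_bbox(mask: np.ndarray) -> tuple[float, float, float, float]:
    """(x0, y0, x1, y1) bounding box of the mask."""
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty foreground mask")
    return float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max())


def bbox_corners(box: tuple[float, float, float, float]) -> np.ndarray:
    x0, y0, x1, y1 = box
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])


def bbox_diagonal(box: tuple[float, float, float, float]) -> float:
    x0, y0, x1, y1 = box
    return float(np.hypot(x1 - x0, y1 - y0))


def foreground_boxes(masks: np.ndarray, start: int, T: int) -> list[tuple[float, float, float, float]]:
    """Per-frame foreground bounding boxes over a CMP subsequence."""
    return [mask_bbox(masks[t]) for t in range(start, start + T)]


def modified_ts_descriptor(traj: Trajectory, start: int, T: int, mask: np.ndarray) -> np.ndarray:
    """Trajectory-shape descriptor augmented with a center-of-mass offset.

    Concatenates the T-1 frame-to-frame displacement vectors with the vector
    from the trajectory's start point to the foreground center of mass at the
    start frame, the latter divided by the diagonal of the mask bounding box
    (scale invariance). Length 2(T-1)+2.
    """
    if not traj.alive(start, start + T):
        raise ValueError("trajectory does not span the descriptor window")
    i0 = start - traj.start_frame
    pts = traj.points[i0 : i0 + T]
    disp = np.diff(pts, axis=0).ravel()
    com = mask_center_of_mass(mask)
    diag = bbox_diagonal(mask_bbox(mask))
    offset = (com - pts[0]) / diag
    return np.concatenate([disp, offset])


def match_trajectories(
    seq1_trajs: list[Trajectory],
    seq2_trajs: list[Trajectory],
    start1: int,
    start2: int,
    T: int,
    mask1: np.ndarray,
    mask2: np.ndarray,
) -> list[TrajectoryMatch]:
    """Nearest-neighbor matching of trajectory descriptors across sequences.

    Only trajectories spanning the full T-frame window, starting at the
    sequence's start frame, participate; every eligible sequence-1 trajectory
    is matched to its nearest sequence-2 neighbor (many-to-one allowed). The
    same-start constraint means corresponding points share their within-CMP
    frame index.
    """
    el1 = [t for t in seq1_trajs if t.alive(start1, start1 + T)]
    el2 = [t for t in seq2_trajs if t.alive(start2, start2 + T)]
    if not el1 or not el2:
        return []
    D1 = np.stack([modified_ts_descriptor(t, start1, T, mask1) for t in el1])
    D2 = np.stack([modified_ts_descriptor(t, start2, T, mask2) for t in el2])
    matches = []
    for i, t1 in enumerate(el1):
        d = np.linalg.norm(D2 - D1[i], axis=1)
        j = int(np.argmin(d))
        t2 = el2[j]
        matches.append(
            TrajectoryMatch(
                id1=t1.id,
                id2=t2.id,
                distance=float(d[j]),
                points1=t1.points[start1 - t1.start_frame :][:T].copy(),
                points2=t2.points[start2 - t2.start_frame :][:T].copy(),
            )
        )
    return matches


# ---------------------------------------------------------------------------
# homography estimation


def _normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity normalizing points to zero mean, mean distance sqrt(2)."""
    c = pts.mean(axis=0)
    scale = np.sqrt(2) / max(np.linalg.norm(pts - c, axis=1).mean(), 1e-12)
    Tm = np.array([[scale, 0, -scale * c[0]], [0, scale, -scale * c[1]], [0, 0, 1]])
    return Tm


def fit_homography_lstsq(src: np.ndarray, dst: np.ndarray, weights: np.ndarray | None = None) -> Homography | None:
    """Direct linear transform: least-squares H with dst ~ H src.

    Uses Hartley normalization and the SVD null vector of the stacked DLT
    system. Returns None for degenerate configurations.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if len(src) < 4:
        return None
    Ts, Td = _normalization(src), _normalization(dst)
    s = (np.hstack([src, np.ones((len(src), 1))]) @ Ts.T)
    d = (np.hstack([dst, np.ones((len(dst), 1))]) @ Td.T)
    n = len(src)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:3] = s
    A[0::2, 6:9] = -d[:, 0:1] * s
    A[1::2, 3:6] = s
    A[1::2, 6:9] = -d[:, 1:2] * s
    if weights is not None:
        w = np.repeat(np.sqrt(np.asarray(weights, float)), 2)
        A = A * w[:, None]
    try:
        _, sv, Vt = np.linalg.svd(A)
    except np.linalg.LinAlgError:
        return None
    if sv[-2] < 1e-12:  # rank deficient: collinear sample
        return None
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    if abs(np.linalg.det(H)) < 1e-12:
        return None
    return Homography(H)


def _reprojection_errors(H: Homography, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    return np.linalg.norm(H.apply(src) - dst, axis=1)


def fit_homography(
    matches: list[TrajectoryMatch],
    fg_boxes1: list[tuple[float, float, float, float]] | None = None,
    fg_boxes2: list[tuple[float, float, float, float]] | None = None,
    mode: str = "tm",
    use_fg: bool = False,
    max_outlier_fraction: float = 1.0,
    inlier_threshold: float | None = None,
    seed: int = 0,
    max_iterations: int = 2000,
    confidence: float = 0.99,
) -> HomographyAlignment | None:
    """RANSAC homography from trajectory matches, u = H v (seq2 -> seq1).

    ``mode``: "im" samples 4 point correspondences per iteration; "tm"
    samples 4 trajectory matches and solves the 4T-point least-squares
    system. A TM match is an inlier iff more than half of its point
    correspondences reproject within the pixel threshold (default: 0.05 x
    the mean foreground-box diagonal of sequence 1). With ``use_fg``, the
    per-frame box-corner correspondences join every least-squares objective
    with unit weight; with no matches at all this degenerates to the
    box-only fit. Returns None when the best model's outlier fraction
    exceeds ``max_outlier_fraction``. Deterministic given ``seed``.
    """
    if mode not in ("im", "tm"):
        raise ValueError("mode must be 'im' or 'tm'")
    rng = np.random.default_rng(seed)

    fg_src = fg_dst = None
    if use_fg:
        if fg_boxes1 is None or fg_boxes2 is None:
            raise ValueError("use_fg requires per-frame foreground boxes for both sequences")
        fg_dst = np.concatenate([bbox_corners(b) for b in fg_boxes1])
        fg_src = np.concatenate([bbox_corners(b) for b in fg_boxes2])

    if inlier_threshold is None:
        if fg_boxes1:
            inlier_threshold = 0.05 * float(np.mean([bbox_diagonal(b) for b in fg_boxes1]))
        elif matches:
            pts = np.concatenate([m.points1 for m in matches])
            span = pts.max(axis=0) - pts.min(axis=0)
            inlier_threshold = 0.05 * float(np.hypot(*span))
        else:
            raise ValueError("cannot derive an inlier threshold without boxes or matches")

    if not matches:
        if not use_fg:
            return None
        H = fit_homography_lstsq(fg_src, fg_dst)
        if H is None:
            return None
        return HomographyAlignment(H, mode=mode, inlier_matches=[], outlier_fraction=0.0, fg_regularized=True)

    src_pts = np.concatenate([m.points2 for m in matches])
    dst_pts = np.concatenate([m.points1 for m in matches])
    T = len(matches[0].points1)
    n_units = len(src_pts) if mode == "im" else len(matches)
    if (mode == "im" and len(src_pts) < 4) or (mode == "tm" and len(matches) < 4):
        return None

    def solve(sample_src, sample_dst):
        if use_fg:
            sample_src = np.concatenate([sample_src, fg_src])
            sample_dst = np.concatenate([sample_dst, fg_dst])
        return fit_homography_lstsq(sample_src, sample_dst)

    def count_inliers(H):
        err = _reprojection_errors(H, src_pts, dst_pts)
        pt_in = err < inlier_threshold
        if mode == "im":
            return int(pt_in.sum()), pt_in
        per_match = pt_in.reshape(len(matches), T)
        m_in = per_match.sum(axis=1) > T / 2
        return int(m_in.sum()), m_in

    best = None
    best_in = -1
    best_flags = None
    iters = max_iterations
    done = 0
    while done < iters:
        done += 1
        if mode == "im":
            idx = rng.choice(len(src_pts), size=4, replace=False)
            H = solve(src_pts[idx], dst_pts[idx])
        else:
            idx = rng.choice(len(matches), size=4, replace=False)
            s = np.concatenate([matches[i].points2 for i in idx])
            d = np.concatenate([matches[i].points1 for i in idx])
            H = solve(s, d)
        if H is None:
            continue  # degenerate (e.g. collinear) sample: resample
        n_in, flags = count_inliers(H)
        if n_in > best_in:
            best_in, best, best_flags = n_in, H, flags
            # adaptive iteration count at the requested confidence
            w = max(n_in / n_units, 1e-9)
            with np.errstate(divide="ignore"):
                need = np.log(1 - confidence) / np.log(max(1 - w**4, 1e-12))
            iters = min(max_iterations, int(np.ceil(need)) if np.isfinite(need) else max_iterations)
    if best is None or best_in == 0:
        return None

    # final least-squares refit on all inliers (+ fg corners when requested)
    if mode == "im":
        refit_src, refit_dst = src_pts[best_flags], dst_pts[best_flags]
        inlier_ids = list(np.nonzero(best_flags)[0])
    else:
        inlier_ids = list(np.nonzero(best_flags)[0])
        refit_src = np.concatenate([matches[i].points2 for i in inlier_ids])
        refit_dst = np.concatenate([matches[i].points1 for i in inlier_ids])
    H_ref = solve(refit_src, refit_dst)
    if H_ref is not None:
        n_in, flags = count_inliers(H_ref)
        if n_in >= best_in:
            best, best_in, best_flags = H_ref, n_in, flags
            inlier_ids = list(np.nonzero(flags)[0])

    outlier_fraction = 1.0 - best_in / n_units
    if outlier_fraction > max_outlier_fraction:
        return None
    return HomographyAlignment(
        homography=best,
        mode=mode,
        inlier_matches=inlier_ids,
        outlier_fraction=float(outlier_fraction),
        fg_regularized=use_fg,
    )
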