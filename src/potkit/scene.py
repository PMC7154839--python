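"""Synthetic articulated scenes with analytically consistent motion channels.

The generator renders a 2-D side-view quadruped — 11 rigid capsule segments
(torso, neck, head and four two-segment legs) — whose joint angles are driven
by behavior programs (walking, running, pausing, head-turning, sitting). Every
downstream input of the pipeline is produced from the same kinematic model:

* binary foreground masks (union of the capsules),
* dense optical flow, computed per pixel from the rigid frame-to-frame motion
  of the capsule owning that pixel (so the flow is exact, not estimated),
* dense point trajectories, obtained by advecting seed points through that
  flow — which makes the flow/trajectory consistency exact by construction,
* named landmarks (nose, eye, shoulder, hip, knees, feet) with visibility,
* per-frame behavior labels.

Gait programs are built so that one gait period translates the body by an
integer number of pixels that is a multiple of the trajectory seeding grid.
The rasterized scene at ``t + period`` is then an exact translate of the scene
at ``t``, which makes limb trajectories exactly periodic after removing the
body translation — a property the temporal-partitioning tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Shot, Trajectory
from .mappings import bilinear_sample

# ---------------------------------------------------------------------------
# skeleton geometry (px)

TORSO_LEN = 56.0
NECK_LEN = 22.0
HEAD_LEN = 18.0
UPPER_LEG_LEN = 20.0
LOWER_LEG_LEN = 20.0

_RADII = {
    "torso": 9.0,
    "neck": 5.0,
    "head": 6.0,
    "upper": 4.0,
    "lower": 3.5,
}

LEGS = ("fl", "fr", "bl", "br")  # front/back x left/right

#: drawing order; lower depth occludes higher (right-side legs are nearest)
SEGMENT_DEPTH = {
    "leg_fr_lower": 0,
    "leg_fr_upper": 1,
    "leg_br_lower": 2,
    "leg_br_upper": 3,
    "head": 4,
    "neck": 5,
    "torso": 6,
    "leg_fl_upper": 7,
    "leg_fl_lower": 8,
    "leg_bl_upper": 9,
    "leg_bl_lower": 10,
}

SEGMENT_NAMES = tuple(sorted(SEGMENT_DEPTH, key=SEGMENT_DEPTH.get))

LEG_SEGMENTS = tuple(n for n in SEGMENT_NAMES if n.startswith("leg_"))

#: per-segment gray level for the shaded rendering; a multiplicative shuffle
#: of the depth order keeps neighboring segments at contrasting shades, so
#: internal part boundaries (leg against torso, head against neck) produce
#: image edges the way a textured animal would
_SEGMENT_SHADE = {n: 0.25 + 0.7 * ((5 * SEGMENT_DEPTH[n]) % 11) / 10.0 for n in SEGMENT_NAMES}

_NECK_BASE_ANGLE = -0.9  # rad from +x axis; y points down, so this is up-forward
_HEAD_BEND = 0.7

_REST_ANGLES = {"torso_pitch": 0.0, "neck": 0.0, "head": 0.0}
for _leg in LEGS:
    _REST_ANGLES[f"hip_{_leg}"] = 0.0
    _REST_ANGLES[f"knee_{_leg}"] = 0.12


# ---------------------------------------------------------------------------
# behavior programs


@dataclass(frozen=True)
class BehaviorProgram:
    """A named motion program driving the skeleton's joints.

    ``joint_angle_functions`` maps joint names to functions of the local frame
    index (frames since the program started). Missing joints hold their rest
    angle. Periodic programs (gaits) state their ``period`` in frames; pause
    programs must produce zero joint and translation velocity.
    """

    name: str
    joint_angle_functions: Mapping[str, Callable[[int], float]]
    period: int | None = None
    translation_velocity: float = 0.0

    def __post_init__(self):
        if self.period is not None and self.period < 5:
            raise ValueError("periodic programs need a period of at least 5 frames")

    def joints(self, local_t: int) -> dict[str, float]:
        t = local_t if self.period is None else local_t % self.period
        angles = dict(_REST_ANGLES)
        for joint, fn in self.joint_angle_functions.items():
            angles[joint] = float(fn(t))
        return angles


def _gait(name: str, period: int, velocity: float, amplitude: float) -> BehaviorProgram:
    w = 2.0 * np.pi / period
    fns: dict[str, Callable[[int], float]] = {}
    # 4-beat footfall phasing: each leg at a distinct quarter-cycle phase, so
    # the gait has no half-period left/right symmetry and its visual period
    # is the full cycle
    for leg, phase in (("fl", 0.0), ("fr", 0.5 * np.pi), ("br", np.pi), ("bl", 1.5 * np.pi)):
        fns[f"hip_{leg}"] = (lambda t, p=phase: amplitude * np.sin(w * t + p))
        fns[f"knee_{leg}"] = (lambda t, p=phase: 0.12 + 0.5 * amplitude * (1 + np.sin(w * t + p + 0.5 * np.pi)) / 2)
    return BehaviorProgram(name, fns, period=period, translation_velocity=velocity)


def walk(period: int = 12, velocity: float = 1.5) -> BehaviorProgram:
    """Walking gait; defaults translate 18 px per 12-frame period."""
    return _gait("walk", period, velocity, amplitude=0.45)


def run(period: int = 6, velocity: float = 3.0) -> BehaviorProgram:
    """Running gait: faster, shorter period, wider leg swing."""
    return _gait("run", period, velocity, amplitude=0.55)


def pause() -> BehaviorProgram:
    """Standing still: all joints at rest, zero translation."""
    return BehaviorProgram("pause", {}, period=None, translation_velocity=0.0)


def head_turn(period: int = 16, amplitude: float = 0.5) -> BehaviorProgram:
    """Standing while oscillating the neck and head."""
    w = 2.0 * np.pi / period
    fns = {
        "neck": lambda t: amplitude * np.sin(w * t),
        "head": lambda t: 0.6 * amplitude * np.sin(w * t + 0.8),
    }
    return BehaviorProgram("head_turn", fns, period=period, translation_velocity=0.0)


def sit(duration: int = 30) -> BehaviorProgram:
    """Aperiodic sitting-down motion: torso pitches up while knees fold."""
    ramp = lambda t: min(t / max(duration - 1, 1), 1.0)
    fns: dict[str, Callable[[int], float]] = {"torso_pitch": lambda t: -0.30 * ramp(t)}
    for leg in ("bl", "br"):
        fns[f"knee_{leg}"] = (lambda t, r=ramp: 0.12 + 0.9 * r(t))
        fns[f"hip_{leg}"] = (lambda t, r=ramp: -0.5 * r(t))
    return BehaviorProgram("sit", fns, period=None, translation_velocity=0.0)


# ---------------------------------------------------------------------------
# forward kinematics


def _rot(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def skeleton_segments(root: np.ndarray, joints: Mapping[str, float]) -> dict[str, tuple[np.ndarray, np.ndarray, float]]:
    """Segment name -> (endpoint a, endpoint b, radius) for one pose."""
    pitch = joints["torso_pitch"]
    R = _rot(pitch)
    hip = np.asarray(root, dtype=float)
    shoulder = hip + R @ np.array([TORSO_LEN, 0.0])
    segs: dict[str, tuple[np.ndarray, np.ndarray, float]] = {
        "torso": (hip, shoulder, _RADII["torso"]),
    }
    neck_angle = pitch + _NECK_BASE_ANGLE + joints["neck"]
    neck_end = shoulder + NECK_LEN * np.array([np.cos(neck_angle), np.sin(neck_angle)])
    segs["neck"] = (shoulder, neck_end, _RADII["neck"])
    head_angle = neck_angle + _HEAD_BEND + joints["head"]
    head_end = neck_end + HEAD_LEN * np.array([np.cos(head_angle), np.sin(head_angle)])
    segs["head"] = (neck_end, head_end, _RADII["head"])
    for leg in LEGS:
        attach = shoulder if leg.startswith("f") else hip
        a_up = pitch + joints[f"hip_{leg}"]
        knee = attach + UPPER_LEG_LEN * np.array([np.sin(a_up), np.cos(a_up)])
        a_lo = a_up + joints[f"knee_{leg}"]
        foot = knee + LOWER_LEG_LEN * np.array([np.sin(a_lo), np.cos(a_lo)])
        segs[f"leg_{leg}_upper"] = (attach, knee, _RADII["upper"])
        segs[f"leg_{leg}_lower"] = (knee, foot, _RADII["lower"])
    return segs


def _landmarks_of(segs: dict) -> dict[str, np.ndarray]:
    neck_a, head_b, _ = segs["head"][0], segs["head"][1], None
    head_dir = head_b - neck_a
    head_dir = head_dir / np.linalg.norm(head_dir)
    perp = np.array([head_dir[1], -head_dir[0]])  # rotate toward -y (up)
    lm = {
        "nose": head_b,
        "eye": neck_a + 0.45 * (head_b - neck_a) + 3.0 * perp,
        "neck_base": segs["torso"][1],
        "hip": segs["torso"][0],
    }
    for leg in LEGS:
        lm[f"knee_{leg}"] = segs[f"leg_{leg}_upper"][1]
        lm[f"foot_{leg}"] = segs[f"leg_{leg}_lower"][1]
    return lm


def _segment_distance_fields(segs: dict, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Distances from every pixel to every segment centerline.

    Returns ``(dist, surf)`` where ``dist[s]`` is the (H, W) point-to-segment
    distance for segment ``s`` (ordered by SEGMENT_NAMES) and ``surf = dist -
    radius`` (negative inside the capsule).
    """
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    P = np.stack([xx, yy], axis=-1).astype(float)  # (H, W, 2)
    dist = np.empty((len(SEGMENT_NAMES), H, W))
    surf = np.empty_like(dist)
    for s, name in enumerate(SEGMENT_NAMES):
        a, b, r = segs[name]
        ab = b - a
        denom = float(ab @ ab)
        ap = P - a
        t = np.clip((ap @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros((H, W))
        closest = a + t[..., None] * ab
        d = np.linalg.norm(P - closest, axis=-1)
        dist[s] = d
        surf[s] = d - r
    return dist, surf


def _point_surface_distance(segs: dict, pts: np.ndarray) -> np.ndarray:
    """min over segments of (distance to centerline - radius), per point."""
    pts = np.atleast_2d(pts)
    best = np.full(len(pts), np.inf)
    for name in SEGMENT_NAMES:
        a, b, r = segs[name]
        ab = b - a
        denom = float(ab @ ab)
        ap = pts - a
        t = np.clip((ap @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(pts))
        d = np.linalg.norm(pts - (a + t[:, None] * ab), axis=1) - r
        best = np.minimum(best, d)
    return best


def _rigid_motion(seg_from, seg_to):
    """Rotation matrix and translation mapping a segment's pose to the next."""
    a1, b1, _ = seg_from
    a2, b2, _ = seg_to
    u1 = (b1 - a1) / np.linalg.norm(b1 - a1)
    u2 = (b2 - a2) / np.linalg.norm(b2 - a2)
    c = float(u1 @ u2)
    s = float(u1[0] * u2[1] - u1[1] * u2[0])
    R = np.array([[c, -s], [s, c]])
    return R, a1, a2


# ---------------------------------------------------------------------------
# scene container


@dataclass
class SyntheticScene:
    """A rendered articulated scene with all pipeline inputs and ground truth."""

    frames: int
    image_size: tuple[int, int]  # (H, W)
    trajectories: list[Trajectory]
    masks: np.ndarray  # (T, H, W) bool
    flow: np.ndarray  # (T-1, H, W, 2) float
    landmarks: pd.DataFrame  # frame, name, x, y, visible
    labels: list[str]  # per-frame behavior name
    trajectory_parts: dict[int, str] = field(default_factory=dict)
    segments: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (T, 2, 2)
    images: np.ndarray | None = None  # (T, H, W) shaded rendering in [0, 1]

    def to_shot(self, shot_id: int = 0) -> Shot:
        return Shot(
            id=shot_id,
            frame_count=self.frames,
            trajectories=list(self.trajectories),
            masks=self.masks,
            flow=self.flow,
            landmarks=self.landmarks,
            images=self.images,
        )

    def landmark_array(self, frame: int) -> pd.DataFrame:
        return self.landmarks[self.landmarks["frame"] == frame]


# ---------------------------------------------------------------------------
# scene generation


def make_scene(
    schedule: Sequence[tuple[BehaviorProgram, int]],
    image_size: tuple[int, int] = (160, 256),
    seed: int = 0,
    root_y: float = 70.0,
    start_x: float | None = None,
    spawn_stride: int = 3,
    spacing_cell: int = 6,
    mask_dilate: int = 0,
    flow_noise: float = 0.0,
) -> SyntheticScene:
    """Render a schedule of behavior programs into a full synthetic scene.

    ``spawn_stride`` and ``spacing_cell`` control trajectory density: seeds are
    placed on a ``spawn_stride``-px grid, at most one live trajectory per
    ``spacing_cell``-px cell. ``mask_dilate`` (px, may be negative for erosion)
    and ``flow_noise`` (px std, i.i.d. Gaussian added to the stored flow) are
    degradation knobs for robustness experiments; both default to clean data.
    """
    H, W = image_size
    T = sum(d for _, d in schedule)
    if T < 2:
        raise ValueError("schedule must cover at least 2 frames")
    for _, d in schedule:
        if d < 1:
            raise ValueError("program durations must be >= 1 frame")
    rng = np.random.default_rng(seed)

    # per-frame pose
    labels: list[str] = []
    roots = np.empty((T, 2))
    all_segs: list[dict] = []
    x = start_x if start_x is not None else 50.0
    t_global = 0
    for prog, dur in schedule:
        for lt in range(dur):
            roots[t_global] = (x, root_y)
            labels.append(prog.name)
            all_segs.append(skeleton_segments(roots[t_global], prog.joints(lt)))
            x += prog.translation_velocity
            t_global += 1

    # bounds check
    for t, segs in enumerate(all_segs):
        for name, (a, b, r) in segs.items():
            for p in (a, b):
                if not (r <= p[0] <= W - 1 - r and r <= p[1] <= H - 1 - r):
                    raise ValueError(f"skeleton leaves the image at frame {t} (segment {name})")

    depth = np.array([SEGMENT_DEPTH[n] for n in SEGMENT_NAMES], dtype=float)

    masks = np.zeros((T, H, W), dtype=bool)
    images = np.zeros((T, H, W))
    flow = np.zeros((T - 1, H, W, 2))
    shade = np.array([_SEGMENT_SHADE[n] for n in SEGMENT_NAMES])
    owners: list[np.ndarray] = []
    surfs: list[np.ndarray] = []
    for t in range(T):
        dist, surf = _segment_distance_fields(all_segs[t], (H, W))
        inside = surf <= 0
        masks[t] = inside.any(axis=0)
        # ownership: topmost capsule containing the pixel, else nearest surface
        key = np.where(inside, depth[:, None, None], 1000.0 + surf)
        owners.append(np.argmin(key, axis=0))
        surfs.append(surf.min(axis=0))
        images[t] = np.where(masks[t], shade[owners[t]], 0.0)

    for t in range(T - 1):
        band = surfs[t] <= 2.0
        for s, name in enumerate(SEGMENT_NAMES):
            sel = band & (owners[t] == s)
            if not sel.any():
                continue
            R, a1, a2 = _rigid_motion(all_segs[t][name], all_segs[t + 1][name])
            ys, xs = np.nonzero(sel)
            p = np.stack([xs, ys], axis=1).astype(float)
            moved = (p - a1) @ R.T + a2
            flow[t][ys, xs] = moved - p

    # trajectories by advection through the generated flow
    active: list[dict] = []
    done: list[dict] = []
    next_id = 0
    for t in range(T):
        if t > 0 and active:
            pts = np.array([tr["pts"][-1] for tr in active])
            moved = pts + bilinear_sample(flow[t - 1], pts)
            safe = _point_surface_distance(all_segs[t], moved)
            keep = []
            for tr, p, s in zip(active, moved, safe):
                if s <= -1.0 and 1 <= p[0] <= W - 2 and 1 <= p[1] <= H - 2:
                    tr["pts"].append(p)
                    keep.append(tr)
                else:
                    done.append(tr)
            active = keep
        if t <= T - 2:
            occupied = set()
            for tr in active:
                p = tr["pts"][-1]
                occupied.add((int(p[0] // spacing_cell), int(p[1] // spacing_cell)))
            dist, surf = None, surfs[t]
            cand_y, cand_x = np.nonzero(surf[::spawn_stride, ::spawn_stride] <= -1.5)
            for cy, cx in zip(cand_y, cand_x):
                px, py = cx * spawn_stride, cy * spawn_stride
                cell = (px // spacing_cell, py // spacing_cell)
                if cell in occupied:
                    continue
                occupied.add(cell)
                part = SEGMENT_NAMES[owners[t][py, px]]
                active.append({"id": next_id, "start": t, "pts": [np.array([px, py], float)], "part": part})
                next_id += 1
    done.extend(active)

    trajectories = []
    parts = {}
    for tr in sorted(done, key=lambda d: d["id"]):
        if len(tr["pts"]) < 2:
            continue
        trajectories.append(Trajectory(tr["id"], tr["start"], np.array(tr["pts"])))
        parts[tr["id"]] = tr["part"]

    # landmarks
    rows = []
    for t in range(T):
        for name, p in _landmarks_of(all_segs[t]).items():
            rows.append((t, name, p[0], p[1], True))
    landmarks = pd.DataFrame(rows, columns=["frame", "name", "x", "y", "visible"])

    segments = {
        name: np.stack([np.stack([all_segs[t][name][0], all_segs[t][name][1]]) for t in range(T)])
        for name in SEGMENT_NAMES
    }

    if mask_dilate:
        from scipy import ndimage

        op = ndimage.binary_dilation if mask_dilate > 0 else ndimage.binary_erosion
        masks = np.stack([op(m, iterations=abs(mask_dilate)) for m in masks])
    if flow_noise > 0:
        flow = flow + rng.normal(0.0, flow_noise, size=flow.shape)

    return SyntheticScene(
        frames=T,
        image_size=(H, W),
        trajectories=trajectories,
        masks=masks,
        flow=flow,
        landmarks=landmarks,
        labels=labels,
        trajectory_parts=parts,
        segments=segments,
        images=images,
    )


# ---------------------------------------------------------------------------
# warping


def _check_invertible(mapping, inverse, image_size: tuple[int, int]) -> None:
    H, W = image_size
    gy, gx = np.mgrid[0 : H : 8, 0 : W : 8]
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(float)
    err = np.linalg.norm(inverse.apply(mapping.apply(grid)) - grid, axis=1)
    if not np.all(np.isfinite(err)) or err.max() > 0.5:
        raise ValueError("mapping is not invertible over the image domain")


def warp_scene(scene: SyntheticScene, mapping, noise_px: float = 0.0, seed: int = 0) -> SyntheticScene:
    """Map a scene through an invertible plane warp, with optional point noise.

    All geometric entities (trajectory points, landmarks, mask, flow) are
    mapped consistently: the warped flow at pixel q is
    ``warp(p + flow(p)) - q`` with ``p = warp^-1(q)``, so the warped scene
    satisfies the same flow/trajectory consistency as the original. Positional
    noise (i.i.d. Gaussian, ``noise_px`` std) is added to trajectories and
    landmarks only. Behavior labels are preserved.
    """
    if hasattr(mapping, "inverse"):
        inverse = mapping.inverse()
    elif hasattr(mapping, "numeric_inverse"):
        inverse = mapping.numeric_inverse(scene.image_size)
    else:
        raise ValueError("mapping must provide inverse() or numeric_inverse()")
    _check_invertible(mapping, inverse, scene.image_size)

    rng = np.random.default_rng(seed)
    Hh, Ww = scene.image_size
    T = scene.frames

    trajs = []
    for tr in scene.trajectories:
        pts = mapping.apply(tr.points)
        if noise_px > 0:
            pts = pts + rng.normal(0.0, noise_px, size=pts.shape)
        trajs.append(Trajectory(tr.id, tr.start_frame, pts))

    lm = scene.landmarks.copy()
    warped_pts = mapping.apply(lm[["x", "y"]].to_numpy())
    if noise_px > 0:
        warped_pts = warped_pts + rng.normal(0.0, noise_px, size=warped_pts.shape)
    lm["x"], lm["y"] = warped_pts[:, 0], warped_pts[:, 1]
    lm["visible"] = lm["visible"] & (
        (lm["x"] >= 0) & (lm["x"] <= Ww - 1) & (lm["y"] >= 0) & (lm["y"] <= Hh - 1)
    )

    gy, gx = np.mgrid[0:Hh, 0:Ww]
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(float)
    src = inverse.apply(grid)  # p = warp^-1(q)
    sx = np.clip(np.round(src[:, 0]).astype(int), 0, Ww - 1)
    sy = np.clip(np.round(src[:, 1]).astype(int), 0, Hh - 1)
    in_dom = (src[:, 0] >= -0.5) & (src[:, 0] <= Ww - 0.5) & (src[:, 1] >= -0.5) & (src[:, 1] <= Hh - 0.5)

    masks = np.zeros_like(scene.masks)
    images = None if scene.images is None else np.zeros_like(scene.images)
    for t in range(T):
        masks[t] = (scene.masks[t][sy, sx] & in_dom).reshape(Hh, Ww)
        if images is not None:
            images[t] = (scene.images[t][sy, sx] * in_dom).reshape(Hh, Ww)

    flow = np.zeros_like(scene.flow)
    base = mapping.apply(src)
    for t in range(T - 1):
        f_src = bilinear_sample(scene.flow[t], src)
        # displacement between warped positions: exactly zero wherever the
        # source flow is zero, regardless of numeric-inverse residual
        flow[t] = (mapping.apply(src + f_src) - base).reshape(Hh, Ww, 2)

    segments = {name: mapping.apply(arr.reshape(-1, 2)).reshape(arr.shape) for name, arr in scene.segments.items()}

    return SyntheticScene(
        frames=T,
        image_size=scene.image_size,
        trajectories=trajs,
        masks=masks,
        flow=flow,
        landmarks=lm,
        labels=list(scene.labels),
        trajectory_parts=dict(scene.trajectory_parts),
        segments=segments,
        images=images,
    )
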