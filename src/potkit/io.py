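"""Readers and writers for the on-disk formats the pipeline touches.

Conventions used throughout the package: pixel units with x pointing right and
y pointing down, origin at the top-left pixel center; frame indices are 0-based;
temporal intervals are half-open ``[start, end)``.

Formats:

* trajectories — plain text, one trajectory per line:
  ``id start_frame x0 y0 x1 y1 ...``
* masks — a directory of ``mask_%05d.png`` files or a single ``.npz`` archive
  with key ``masks`` (T, H, W) of {0, 1}
* flow — ``.npz`` archive with key ``flow`` of shape (T-1, H, W, 2), channels
  (u, v) in px/frame, where ``flow[t]`` is the displacement from frame t to t+1
* landmarks — CSV with columns ``frame, name, x, y, visible``
* labels / intervals / clusters / CMPs / alignments — JSON with a
  ``schema_version`` field
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

SCHEMA_VERSION = 1

# 8-connectivity structuring element for component labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Trajectory:
    """A point tracked over consecutive frames.

    ``points[k]`` is the (x, y) position at frame ``start_frame + k``.
    """

    id: int
    start_frame: int
    points: np.ndarray  # (L, 2) float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("trajectory points must be an (L, 2) array")
        if len(self.points) < 2:
            raise ValueError("trajectory must span at least 2 frames")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("trajectory coordinates must be finite")

    @property
    def end_frame(self) -> int:
        """First frame past the trajectory (half-open span)."""
        return self.start_frame + len(self.points)

    def alive(self, start: int, end: int) -> bool:
        """True if the trajectory has a point at every frame of [start, end)."""
        return self.start_frame <= start and self.end_frame >= end

    def point_at(self, frame: int) -> np.ndarray:
        return self.points[frame - self.start_frame]


@dataclass
class Interval:
    """Half-open frame range within a shot; the unit of behavior clustering."""

    shot_id: int
    start: int
    end: int
    label: str | None = None

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Shot:
    """A contiguous frame sequence without scene transitions, plus its inputs."""

    id: int
    frame_count: int
    trajectories: list[Trajectory] = field(default_factory=list)
    masks: np.ndarray | None = None  # (T, H, W) bool
    flow: np.ndarray | None = None  # (T-1, H, W, 2) float
    landmarks: pd.DataFrame | None = None
    images: np.ndarray | None = None  # (T, H, W) grayscale in [0, 1]

    def __post_init__(self):
        if self.masks is not None:
            self.masks = np.asarray(self.masks, dtype=bool)
            if self.masks.shape[0] != self.frame_count:
                raise ValueError("masks must have one entry per frame")
        if self.flow is not None:
            self.flow = np.asarray(self.flow, dtype=float)
            if self.flow.shape[0] != self.frame_count - 1:
                raise ValueError("flow must have frame_count - 1 entries")
            if self.masks is not None and self.flow.shape[1:3] != self.masks.shape[1:3]:
                raise ValueError("flow and mask dimensions disagree")


# ---------------------------------------------------------------------------
# trajectories


def write_trajectories(trajs: list[Trajectory], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in trajs:
            coords = " ".join(f"{v:.6f}" for v in t.points.ravel())
            fh.write(f"{t.id} {t.start_frame} {coords}\n")


def read_trajectories(path: str | os.PathLike) -> list[Trajectory]:
    trajs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) < 6:
                raise ValueError(f"{path}:{lineno}: trajectory needs id, start and >= 2 points")
            try:
                tid, start = int(tokens[0]), int(tokens[1])
                coords = np.array([float(v) for v in tokens[2:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable token ({exc})") from None
            if coords.size % 2:
                raise ValueError(f"{path}:{lineno}: odd coordinate count")
            trajs.append(Trajectory(tid, start, coords.reshape(-1, 2)))
    return trajs


# ---------------------------------------------------------------------------
# masks / flow / landmarks / labels


def write_masks(masks: np.ndarray, path: str | os.PathLike) -> None:
    """Write masks either as an NPZ archive (path ends in .npz) or a PNG dir."""
    masks = np.asarray(masks, dtype=bool)
    if str(path).endswith(".npz"):
        np.savez_compressed(path, masks=masks.astype(np.uint8))
    else:
        os.makedirs(path, exist_ok=True)
        for t, m in enumerate(masks):
            iio.imwrite(os.path.join(path, f"mask_{t:05d}.png"), m.astype(np.uint8) * 255)


def read_masks(path: str | os.PathLike) -> np.ndarray:
    if str(path).endswith(".npz"):
        with np.load(path) as npz:
            return npz["masks"].astype(bool)
    files = sorted(f for f in os.listdir(path) if f.endswith(".png"))
    if not files:
        raise FileNotFoundError(f"no mask PNGs in {path}")
    frames = [iio.imread(os.path.join(path, f)) > 127 for f in files]
    shapes = {m.shape for m in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent mask dimensions in {path}: {shapes}")
    return np.stack(frames)


def write_flow(flow: np.ndarray, path: str | os.PathLike) -> None:
    np.savez_compressed(path, flow=np.asarray(flow, dtype=np.float32))


def read_flow(path: str | os.PathLike) -> np.ndarray:
    with np.load(path) as npz:
        flow = npz["flow"].astype(float)
    if flow.ndim != 4 or flow.shape[-1] != 2:
        raise ValueError(f"flow archive must hold a (T-1, H, W, 2) array, got {flow.shape}")
    return flow


def write_landmarks(landmarks: pd.DataFrame, path: str | os.PathLike) -> None:
    landmarks[["frame", "name", "x", "y", "visible"]].to_csv(path, index=False)


def read_landmarks(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "name", "x", "y", "visible"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    df["visible"] = df["visible"].astype(bool)
    return df


def write_labels(labels: list[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION, "labels": list(labels)}, fh)


def read_labels(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return json.load(fh)["labels"]


def write_intervals(intervals: list[Interval], path: str | os.PathLike) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "intervals": [
            {"shot_id": int(iv.shot_id), "start": int(iv.start), "end": int(iv.end), "label": iv.label}
            for iv in intervals
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_intervals(path: str | os.PathLike) -> list[Interval]:
    with open(path) as fh:
        payload = json.load(fh)
    return [Interval(d["shot_id"], d["start"], d["end"], d.get("label")) for d in payload["intervals"]]


def write_json(obj: dict, path: str | os.PathLike) -> None:
    obj = {"schema_version": SCHEMA_VERSION, **obj}
    with open(path, "w") as fh:
        json.dump(obj, fh, default=_json_default)


def read_json(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# preprocessing rules


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Multiple moving objects leave several blobs in the foreground mask; the
    largest one typically corresponds to the object of interest. Ties are
    broken in favor of the component whose first pixel in row-major order
    comes first. An all-zero mask is returned unchanged.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    labelled, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        warnings.warn("all-zero foreground mask", stacklevel=2)
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(mask, labelled, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1  # argmax keeps the first maximum
    # np.argmax ties resolve to the lowest label; scipy labels components in
    # row-major order of their first pixel, which is exactly the tie rule.
    return labelled == best


def split_shots(frame_histograms: np.ndarray, threshold: float) -> list[Interval]:
    """Split a frame range into shots by thresholding histogram differences.

    ``frame_histograms`` holds one L1-normalized color histogram per frame; a
    boundary is placed between frames t-1 and t whenever the L1 difference of
    their histograms exceeds ``threshold``. The returned intervals partition
    ``[0, n_frames)``.
    """
    hists = np.asarray(frame_histograms, dtype=float)
    n = len(hists)
    diffs = np.abs(np.diff(hists, axis=0)).sum(axis=1)
    cuts = [0] + [t + 1 for t in np.nonzero(diffs > threshold)[0]] + [n]
    return [Interval(shot_id=i, start=a, end=b) for i, (a, b) in enumerate(zip(cuts[:-1], cuts[1:]))]


# ---------------------------------------------------------------------------
# shot directories


def write_shot(shot: Shot, directory: str | os.PathLike) -> None:
    """Write every available component of a shot into a directory."""
    os.makedirs(directory, exist_ok=True)
    write_trajectories(shot.trajectories, os.path.join(directory, "trajectories.txt"))
    if shot.masks is not None:
        write_masks(shot.masks, os.path.join(directory, "masks.npz"))
    if shot.flow is not None:
        write_flow(shot.flow, os.path.join(directory, "flow.npz"))
    if shot.landmarks is not None:
        write_landmarks(shot.landmarks, os.path.join(directory, "landmarks.csv"))
    with open(os.path.join(directory, "shot.json"), "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION, "id": shot.id, "frame_count": shot.frame_count}, fh)


def read_shot(directory: str | os.PathLike) -> Shot:
    with open(os.path.join(directory, "shot.json")) as fh:
        meta = json.load(fh)
    masks = flow = landmarks = None
    if os.path.exists(os.path.join(directory, "masks.npz")):
        masks = read_masks(os.path.join(directory, "masks.npz"))
    if os.path.exists(os.path.join(directory, "flow.npz")):
        flow = read_flow(os.path.join(directory, "flow.npz"))
    if os.path.exists(os.path.join(directory, "landmarks.csv")):
        landmarks = read_landmarks(os.path.join(directory, "landmarks.csv"))
    return Shot(
        id=meta["id"],
        frame_count=meta["frame_count"],
        trajectories=read_trajectories(os.path.join(directory, "trajectories.txt")),
        masks=masks,
        flow=flow,
        landmarks=landmarks,
    )
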