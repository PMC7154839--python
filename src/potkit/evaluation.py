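"""Evaluation metrics: clustering quality, interval uniformity, landmark
alignment error with the correctness rule, alignability, precision-recall.

Clustering is scored by purity (fraction of items whose label matches the
most frequent label of their cluster) and the adjusted Rand index (chance-
corrected agreement; random assignments score near 0). Partitioning is scored
by uniformity (fraction of an interval's frames carrying its most frequent
behavior label). Alignments are scored against ground-truth landmarks: each
landmark is mapped into the other sequence and back, the two distances are
normalized by the object scale of their target frame (the maximum pairwise
landmark distance) and averaged; an alignment is *correct* when the mean
error is below 0.18 and the IOU of the visible-landmark sets exceeds 0.5
(which refuses credit for accidental alignments of a few landmarks).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .homography import fit_homography_lstsq, HomographyAlignment
from .tps import apply_mapping

__all__ = [
    "purity",
    "ari",
    "uniformity",
    "behavior_counts",
    "alignment_error",
    "AlignmentVerdict",
    "verdict",
    "alignable_oracle",
    "precision_recall",
]

ERROR_THRESHOLD = 0.18
IOU_THRESHOLD = 0.5


def purity(assignments, labels) -> float:
    """Fraction of items whose label is the most frequent one in their cluster."""
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if len(assignments) == 0 or len(assignments) != len(labels):
        raise ValueError("assignments and labels must be equal-length and nonempty")
    correct = 0
    for c in np.unique(assignments):
        members = labels[assignments == c]
        correct += Counter(members.tolist()).most_common(1)[0][1]
    return correct / len(labels)


def ari(assignments, labels) -> float:
    """Adjusted Rand index (standard chance-corrected formula)."""
    if len(assignments) == 0 or len(assignments) != len(labels):
        raise ValueError("assignments and labels must be equal-length and nonempty")
    return float(adjusted_rand_score(labels, assignments))


def uniformity(frame_labels) -> float:
    """Fraction of frames carrying the interval's most frequent label."""
    labels = list(frame_labels)
    if not labels:
        raise ValueError("interval has no frames")
    return Counter(labels).most_common(1)[0][1] / len(labels)


def behavior_counts(intervals_with_labels: list[tuple[int, str]]) -> dict[str, int]:
    """Count discovered behaviors, at most once per (shot, behavior).

    ``intervals_with_labels`` holds (shot_id, majority_label) pairs. Counting
    a behavior only once per shot stops a method from inflating its counts by
    splitting one continuous behavior into many pieces.
    """
    seen = set()
    counts: Counter = Counter()
    for shot_id, label in intervals_with_labels:
        if (shot_id, label) not in seen:
            seen.add((shot_id, label))
            counts[label] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# alignment metrics


def _frame_landmarks(landmarks: pd.DataFrame, frame: int) -> pd.DataFrame:
    return landmarks[(landmarks["frame"] == frame) & landmarks["visible"]]


def landmark_scale(frame_lm: pd.DataFrame) -> float:
    """Object scale: maximum pairwise distance among visible landmarks."""
    pts = frame_lm[["x", "y"]].to_numpy()
    if len(pts) < 2:
        raise ValueError("scale needs at least 2 visible landmarks")
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return float(d.max())


def alignment_error(
    alignment,
    landmarks_1: pd.DataFrame,
    landmarks_2: pd.DataFrame,
    frames_1: list[int],
    frames_2: list[int],
) -> float:
    """Mean normalized symmetric landmark error of a CMP alignment.

    For each frame pair and each landmark visible in both sequences, the
    sequence-2 landmark is mapped into sequence 1 (forward, u = f(v)) and
    compared to its annotated position, normalized by the sequence-1 frame's
    object scale; the reverse direction is normalized by the sequence-2
    scale; the landmark's error is the average of the two. The overall error
    is the mean over co-visible landmarks over all frames. Landmarks visible
    in only one sequence are skipped; if no frame has a co-visible landmark
    a ValueError flags the CMP as unevaluable.
    """
    errs = []
    for t, (f1, f2) in enumerate(zip(frames_1, frames_2)):
        lm1 = _frame_landmarks(landmarks_1, f1)
        lm2 = _frame_landmarks(landmarks_2, f2)
        common = sorted(set(lm1["name"]) & set(lm2["name"]))
        if len(common) == 0 or len(lm1) < 2 or len(lm2) < 2:
            continue
        scale1 = landmark_scale(lm1)
        scale2 = landmark_scale(lm2)
        p1 = lm1.set_index("name").loc[common, ["x", "y"]].to_numpy()
        p2 = lm2.set_index("name").loc[common, ["x", "y"]].to_numpy()
        fwd = apply_mapping(alignment, p2, frame_t=t, direction="forward")
        rev = apply_mapping(alignment, p1, frame_t=t, direction="reverse")
        e_fwd = np.linalg.norm(fwd - p1, axis=1) / scale1
        e_rev = np.linalg.norm(rev - p2, axis=1) / scale2
        errs.extend(0.5 * (e_fwd + e_rev))
    if not errs:
        raise ValueError("no co-visible landmarks in any frame of the CMP")
    return float(np.mean(errs))


@dataclass
class AlignmentVerdict:
    error: float
    landmark_iou: float
    correct: bool


def landmark_iou(landmarks_1: pd.DataFrame, landmarks_2: pd.DataFrame, frames_1: list[int], frames_2: list[int]) -> float:
    """IOU of the landmark-name sets visible anywhere in each sequence."""
    vis1 = set(landmarks_1[landmarks_1["frame"].isin(frames_1) & landmarks_1["visible"]]["name"])
    vis2 = set(landmarks_2[landmarks_2["frame"].isin(frames_2) & landmarks_2["visible"]]["name"])
    union = vis1 | vis2
    if not union:
        return 0.0
    return len(vis1 & vis2) / len(union)


def verdict(
    error: float,
    landmarks_1: pd.DataFrame,
    landmarks_2: pd.DataFrame,
    frames_1: list[int],
    frames_2: list[int],
) -> AlignmentVerdict:
    """Correct iff error < 0.18 and visible-landmark IOU > 0.5."""
    iou = landmark_iou(landmarks_1, landmarks_2, frames_1, frames_2)
    return AlignmentVerdict(
        error=float(error),
        landmark_iou=float(iou),
        correct=bool(error < ERROR_THRESHOLD and iou > IOU_THRESHOLD),
    )


def alignable_oracle(
    landmarks_1: pd.DataFrame,
    landmarks_2: pd.DataFrame,
    frames_1: list[int],
    frames_2: list[int],
) -> bool:
    """Whether a homography fit to ground-truth landmark pairs is correct.

    This upper-bounds what any global alignment could achieve on the CMP: if
    even the landmark-supervised homography fails the correctness rule, the
    pair is not alignable and should not count against recall.
    """
    src, dst = [], []
    for f1, f2 in zip(frames_1, frames_2):
        lm1 = _frame_landmarks(landmarks_1, f1).set_index("name")
        lm2 = _frame_landmarks(landmarks_2, f2).set_index("name")
        common = sorted(set(lm1.index) & set(lm2.index))
        src.extend(lm2.loc[common, ["x", "y"]].to_numpy())
        dst.extend(lm1.loc[common, ["x", "y"]].to_numpy())
    if len(src) < 4:
        return False
    H = fit_homography_lstsq(np.asarray(src), np.asarray(dst))
    if H is None:
        return False
    alignment = HomographyAlignment(homography=H, mode="oracle")
    try:
        err = alignment_error(alignment, landmarks_1, landmarks_2, frames_1, frames_2)
    except ValueError:
        return False
    return verdict(err, landmarks_1, landmarks_2, frames_1, frames_2).correct


def precision_recall(
    outlier_fractions: list[float | None],
    correct_flags: list[bool],
    alignable_flags: list[bool],
    sweep: list[float],
) -> dict:
    """Precision-recall curve over the allowed-outlier-fraction knob.

    ``outlier_fractions[i]`` is the fitted outlier fraction of CMP i (None if
    the fit failed entirely); at sweep value s the method returns the CMPs
    with outlier fraction <= s. With n returned, c of them correct, and a
    alignable in total: precision = c/n (1 when n = 0, the curve-endpoint
    convention) and recall = c/a (undefined and flagged when a = 0). Average
    precision integrates precision over recall by the trapezoid rule.
    """
    a = int(np.sum(alignable_flags))
    points = []
    for s in sorted(sweep):
        returned = [
            i
            for i, of in enumerate(outlier_fractions)
            if of is not None and of <= s
        ]
        n = len(returned)
        c = int(np.sum([correct_flags[i] for i in returned])) if returned else 0
        precision = c / n if n > 0 else 1.0
        recall = c / a if a > 0 else float("nan")
        points.append({"max_outlier_fraction": s, "n": n, "c": c, "precision": precision, "recall": recall})
    curve = {"points": points, "alignable": a}
    if a > 0:
        rec = [0.0] + [p["recall"] for p in points]
        prec = [1.0] + [p["precision"] for p in points]
        order = np.argsort(rec)
        rec = np.asarray(rec)[order]
        prec = np.asarray(prec)[order]
        curve["average_precision"] = float(np.trapezoid(prec, rec))
    else:
        curve["average_precision"] = float("nan")
    return curve
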