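"""Canned synthetic study collections and an end-to-end runner.

These helpers assemble small, fully labeled collections of synthetic shots
and run the complete pipeline on them — discovery (PoTs, partitioning,
clustering), CMP extraction, spatial alignment and evaluation. They are the
backbone of the worked examples and of the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation as ev
from . import homography as hg
from . import pipeline as pl
from . import pots as pt
from . import scene as sc
from .io import Shot
from .mappings import Homography

__all__ = ["two_behavior_collection", "EndToEndResult", "run_end_to_end"]


def two_behavior_collection(seed: int = 0, frames: int = 60) -> tuple[list[sc.SyntheticScene], list[Shot]]:
    """Six single-behavior shots: three walking, three head-turning.

    One shot per behavior is additionally viewed under a mild similarity
    transform (scaled and shifted), so alignment across instances is not a
    pure translation. Scenes carry ground-truth labels and landmarks.
    """
    scenes = []
    placements = ((36.0, 72.0), (44.0, 78.0), (30.0, 66.0))
    for i, dur in enumerate((frames, frames - 6, frames + 6)):
        x0, y0 = placements[i]
        scenes.append(
            sc.make_scene([(sc.walk(), dur)], seed=seed + i, start_x=x0, root_y=y0, image_size=(176, 320))
        )
    for i, dur in enumerate((frames, frames - 6, frames + 6)):
        x0, y0 = placements[i]
        scenes.append(
            sc.make_scene([(sc.head_turn(), dur)], seed=seed + 10 + i, start_x=x0 + 14, root_y=y0, image_size=(176, 320))
        )

    # re-view one shot of each behavior through a similarity transform
    S = np.array([[1.12, 0.0, -12.0], [0.0, 1.12, -8.0], [0.0, 0.0, 1.0]])
    for idx in (1, 4):
        scenes[idx] = sc.warp_scene(scenes[idx], Homography(S), noise_px=0.3, seed=seed + idx)
    shots = [scene.to_shot(i) for i, scene in enumerate(scenes)]
    return scenes, shots


@dataclass
class EndToEndResult:
    purity: float
    ari: float
    n_intervals: int
    n_clusters: int
    n_cmps: int
    n_aligned: int
    n_correct: int
    n_alignable: int
    mean_interval_uniformity: float
    whole_shot_uniformity: float
    alignment_errors: list[float] = field(default_factory=list)


def run_end_to_end(
    seed: int = 0,
    frames: int = 60,
    codebook_size: int = 128,
    max_cmps_aligned: int = 12,
) -> EndToEndResult:
    """Full pipeline on the six-shot, two-behavior collection.

    Returns clustering quality (purity/ARI of interval majority labels),
    partitioning uniformity against the unpartitioned baseline, and
    alignment outcomes: of the CMPs aligned with the temporal-matching +
    foreground-box homography, how many pass the landmark correctness rule,
    and how many were alignable at all per the landmark-fitted oracle.
    """
    scenes, shots = two_behavior_collection(seed=seed, frames=frames)
    cfg = pl.PipelineConfig(codebook_size=codebook_size, codebook_restarts=4, seed=seed)
    result = pl.discover_behaviors(shots, cfg)

    majority = []
    for iv in result.intervals:
        labs = scenes[iv.shot_id].labels[iv.start : iv.end]
        majority.append(max(set(labs), key=labs.count))
    clustered = [i for i, c in enumerate(result.assignments) if c >= 0]
    k = max(2, len(clustered) // 4)
    from . import clustering as cl

    sub = cl.cluster_intervals(result.interval_bows[clustered], k=k)
    assignments = {i: int(c) for i, c in zip(clustered, sub)}
    labels_used = [majority[i] for i in clustered]
    purity = ev.purity([assignments[i] for i in clustered], labels_used)
    ari = ev.ari([assignments[i] for i in clustered], labels_used)
    result.assignments = np.array([assignments.get(i, -1) for i in range(len(result.intervals))])

    uniformity = float(
        np.mean(
            [
                ev.uniformity(scenes[iv.shot_id].labels[iv.start : iv.end])
                for iv in result.intervals
            ]
        )
    )
    whole = float(np.mean([ev.uniformity(s.labels) for s in scenes]))

    cmps = pl.extract_cluster_cmps(result, cfg)
    cmps = sorted(cmps, key=lambda c: c.score)
    # alignment on the most promising CMPs across different shots
    cross = [c for c in cmps if c.interval_p.shot_id != c.interval_q.shot_id]
    to_align = cross[:max_cmps_aligned]
    shots_by_id = {s.id: s for s in shots}
    n_aligned = n_correct = n_alignable = 0
    errors = []
    for j, cmp_ in enumerate(to_align):
        lm1 = scenes[cmp_.interval_p.shot_id].landmarks
        lm2 = scenes[cmp_.interval_q.shot_id].landmarks
        f1 = list(range(cmp_.start_i, cmp_.start_i + cmp_.T))
        f2 = list(range(cmp_.start_j, cmp_.start_j + cmp_.T))
        if ev.alignable_oracle(lm1, lm2, f1, f2):
            n_alignable += 1
        halign, _ = pl.align_cmp(cmp_, shots_by_id, mode="tm", use_fg=True, refine_ttps=False, seed=seed + j)
        if halign is None:
            continue
        n_aligned += 1
        try:
            err = ev.alignment_error(halign, lm1, lm2, f1, f2)
        except ValueError:
            continue
        errors.append(err)
        if ev.verdict(err, lm1, lm2, f1, f2).correct:
            n_correct += 1

    return EndToEndResult(
        purity=float(purity),
        ari=float(ari),
        n_intervals=len(result.intervals),
        n_clusters=k,
        n_cmps=len(cmps),
        n_aligned=n_aligned,
        n_correct=n_correct,
        n_alignable=n_alignable,
        mean_interval_uniformity=uniformity,
        whole_shot_uniformity=whole,
        alignment_errors=errors,
    )
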