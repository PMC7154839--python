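"""End-to-end orchestration: shots in, aligned CMPs out.

Wires the five stages together with sensible defaults so that examples, the
command line and tests can run the whole system in a few calls:

1. PoT extraction per shot,
2. temporal partitioning into single-behavior intervals,
3. codebook building and complete-linkage clustering of interval BoWs,
4. CMP extraction inside each cluster (PoT channel, optionally + MBH),
5. spatial alignment of each CMP (TM + FG homography, then TTPS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import clustering as cl
from . import cmps as cm
from . import homography as hg
from . import partition as pa
from . import pots as pt
from . import tps
from .io import Interval, Shot

__all__ = ["PipelineConfig", "DiscoveryResult", "discover_behaviors", "extract_cluster_cmps", "align_cmp"]


@dataclass
class PipelineConfig:
    pot: pt.PoTConfig = field(default_factory=pt.PoTConfig)
    partition: pa.PartitionConfig = field(default_factory=pa.PartitionConfig)
    codebook_size: int = 800
    codebook_restarts: int = 8
    mbh_codebook_size: int = 4000
    use_mbh: bool = False
    n_clusters: int | None = None  # default: a fourth of the interval count
    cmp_length: int = 10
    cmps_per_pair: int = 10
    seed: int = 0


@dataclass
class DiscoveryResult:
    shots: list[Shot]
    pots_per_shot: list[list[pt.PoT]]
    stats_per_shot: list[pt.FrameStats]
    codebook: cl.Codebook
    intervals: list[Interval]
    interval_bows: np.ndarray
    assignments: np.ndarray  # cluster label per interval
    empty_intervals: list[int] = field(default_factory=list)

    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i, c in enumerate(self.assignments):
            out.setdefault(int(c), []).append(i)
        return out


def discover_behaviors(shots: list[Shot], config: PipelineConfig = PipelineConfig()) -> DiscoveryResult:
    """Stages 1-3: PoTs, partitioning, codebook, interval clustering.

    Intervals with an empty BoW (no PoTs at all, e.g. covering residual
    motion below the articulation threshold) are excluded from clustering
    and reported in ``empty_intervals``.
    """
    pots_per_shot = [pt.extract_pots(s, config.pot) for s in shots]
    stats_per_shot = [pt.frame_stats(s.flow, s.masks, config.pot) for s in shots]

    all_desc = np.concatenate(
        [pt.descriptor_matrix(p) for p in pots_per_shot if p]
        or [np.empty((0, 2 * (config.pot.n - 1) + 1))]
    )
    if len(all_desc) < config.codebook_size:
        raise ValueError(
            f"only {len(all_desc)} PoT descriptors extracted; need >= codebook size {config.codebook_size}"
        )
    codebook = cl.build_codebook(
        all_desc, V=config.codebook_size, restarts=config.codebook_restarts, seed=config.seed
    )

    intervals: list[Interval] = []
    interval_bows = []
    for shot, pots, stats in zip(shots, pots_per_shot, stats_per_shot):
        bow_t = pa.framewise_bow(pots, codebook, shot.frame_count)
        ivs = pa.partition_shot(shot.frame_count, bow_t, stats, config.partition, shot_id=shot.id)
        for iv in ivs:
            counts = bow_t[iv.start : iv.end].sum(axis=0)
            total = counts.sum()
            intervals.append(iv)
            interval_bows.append(counts / total if total > 0 else counts)
    interval_bows = np.asarray(interval_bows)

    nonempty = [i for i, b in enumerate(interval_bows) if b.sum() > 0]
    empty = [i for i in range(len(intervals)) if i not in nonempty]
    k = config.n_clusters if config.n_clusters is not None else max(1, len(nonempty) // 4)
    labels = np.full(len(intervals), -1)
    if nonempty:
        sub = cl.cluster_intervals(interval_bows[nonempty], k=min(k, len(nonempty)))
        for idx, lab in zip(nonempty, sub):
            labels[idx] = lab
    return DiscoveryResult(
        shots=shots,
        pots_per_shot=pots_per_shot,
        stats_per_shot=stats_per_shot,
        codebook=codebook,
        intervals=intervals,
        interval_bows=interval_bows,
        assignments=labels,
        empty_intervals=empty,
    )


def _interval_channels(result: DiscoveryResult, idx: int, config: PipelineConfig, mbh_codebook=None):
    iv = result.intervals[idx]
    shot_pos = next(i for i, s in enumerate(result.shots) if s.id == iv.shot_id)
    shot = result.shots[shot_pos]
    pots = result.pots_per_shot[shot_pos]
    pot_desc = [p.descriptor for p in pots if iv.start <= p.start_frame < iv.end]
    pot_frames = [p.start_frame for p in pots if iv.start <= p.start_frame < iv.end]
    channels = {
        "pot": cm.frame_bows(
            np.asarray(pot_desc) if pot_desc else np.empty((0, result.codebook.centroids.shape[1])),
            np.asarray(pot_frames, dtype=int),
            result.codebook,
            iv,
        )
    }
    if config.use_mbh and mbh_codebook is not None:
        descs, frames = cm.mbh_descriptors(shot, iv)
        channels["mbh"] = cm.frame_bows(descs, frames, mbh_codebook, iv)
    return shot, channels


def extract_cluster_cmps(
    result: DiscoveryResult,
    config: PipelineConfig = PipelineConfig(),
    mbh_codebook: cl.Codebook | None = None,
) -> list[cm.CMP]:
    """Stage 4: CMPs for every interval pair sharing a cluster."""
    if config.use_mbh and mbh_codebook is None:
        descs = []
        for shot, ivs in (
            (s, [iv for iv in result.intervals if iv.shot_id == s.id]) for s in result.shots
        ):
            for iv in ivs:
                d, _ = cm.mbh_descriptors(shot, iv)
                if len(d):
                    descs.append(d)
        mat = np.concatenate(descs) if descs else np.empty((0, 2 * cm.MBH_BINS))
        V = min(config.mbh_codebook_size, max(2, len(mat) // 4))
        if len(mat) < V:
            raise ValueError("too few MBH descriptors for the MBH codebook")
        mbh_codebook = cl.build_codebook(mat, V=V, restarts=4, seed=config.seed, channel="mbh")

    cache: dict[int, tuple] = {}

    def channels_of(idx):
        if idx not in cache:
            cache[idx] = _interval_channels(result, idx, config, mbh_codebook)
        return cache[idx]

    out: list[cm.CMP] = []
    for cluster, members in sorted(result.clusters().items()):
        if cluster < 0:
            continue
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                _, ch_i = channels_of(i)
                _, ch_j = channels_of(j)
                D = cm.frame_distance_matrix(ch_i, ch_j)
                out.extend(
                    cm.extract_cmps(
                        result.intervals[i],
                        result.intervals[j],
                        D,
                        T=config.cmp_length,
                        top_k=config.cmps_per_pair,
                    )
                )
    return out


def align_cmp(
    cmp: cm.CMP,
    shots_by_id: dict[int, Shot],
    mode: str = "tm",
    use_fg: bool = True,
    refine_ttps: bool = True,
    max_outlier_fraction: float = 1.0,
    seed: int = 0,
    rpm_config: tps.TPSRPMConfig | None = None,
    max_edge_points: int = 200,
) -> tuple[hg.HomographyAlignment | None, tps.TTPSAlignment | None]:
    """Stage 5: homography (TM/IM [+FG]) and optional TTPS refinement."""
    shot1 = shots_by_id[cmp.interval_p.shot_id]
    shot2 = shots_by_id[cmp.interval_q.shot_id]
    T = cmp.T
    i, j = cmp.start_i, cmp.start_j
    boxes1 = hg.foreground_boxes(shot1.masks, i, T)
    boxes2 = hg.foreground_boxes(shot2.masks, j, T)
    matches = hg.match_trajectories(
        shot1.trajectories, shot2.trajectories, i, j, T, shot1.masks[i], shot2.masks[j]
    )
    halign = hg.fit_homography(
        matches,
        boxes1,
        boxes2,
        mode=mode,
        use_fg=use_fg,
        max_outlier_fraction=max_outlier_fraction,
        seed=seed,
    )
    if halign is None or not refine_ttps:
        return halign, None

    edges1 = [
        tps.extract_foreground_edges(
            tps.gradient_edge_strength(shot1.masks[i + t].astype(float)),
            shot1.masks[i + t],
            frame=t,
            max_points=max_edge_points,
            seed=seed,
        )
        for t in range(T)
    ]
    edges2 = [
        tps.extract_foreground_edges(
            tps.gradient_edge_strength(shot2.masks[j + t].astype(float)),
            shot2.masks[j + t],
            frame=t,
            max_points=max_edge_points,
            seed=seed + 1,
        )
        for t in range(T)
    ]
    flow1 = shot1.flow[i : i + T - 1]
    flow2 = shot2.flow[j : j + T - 1]
    cfg = rpm_config if rpm_config is not None else tps.TPSRPMConfig()
    try:
        talign = tps.fit_ttps(edges1, edges2, flow1, flow2, init_homography=halign.homography, config=cfg)
    except ValueError:
        talign = None
    return halign, talign
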