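import numpy as np
import pytest

from potkit import pots as pt
from potkit import scene as sc
from potkit import tps


@pytest.fixture(scope="session")
def walk_scene():
    """A 30-frame walking scene shared by feature/partition tests."""
    return sc.make_scene([(sc.walk(), 30)], seed=11)


@pytest.fixture(scope="session")
def walk_shot(walk_scene):
    return walk_scene.to_shot(0)


@pytest.fixture(scope="session")
def walk_pots(walk_shot):
    return pt.extract_pots(walk_shot, pt.PoTConfig())


@pytest.fixture(scope="session")
def walk_stats(walk_shot):
    return pt.frame_stats(walk_shot.flow, walk_shot.masks, pt.PoTConfig())


@pytest.fixture(scope="session")
def head_turn_scene():
    """A 24-frame head-turn scene: slow, smooth flow; used by alignment tests."""
    return sc.make_scene([(sc.head_turn(), 24)], seed=5)


@pytest.fixture(scope="session")
def strong_warp():
    """A clearly non-projective TPS warp (3x3 control grid, 10 px moves)."""
    gx, gy = np.meshgrid([30.0, 130.0, 230.0], [20.0, 80.0, 140.0])
    ctrl = np.stack([gx.ravel(), gy.ravel()], 1)
    rng = np.random.default_rng(1)
    return tps.fit_tps(ctrl + rng.normal(0, 10, ctrl.shape), ctrl, lam=1e-1)


@pytest.fixture(scope="session")
def warped_pair(head_turn_scene, strong_warp):
    """(original, warped) head-turn scenes related by the strong TPS warp."""
    warped = sc.warp_scene(head_turn_scene, strong_warp, noise_px=0.5, seed=0)
    return head_turn_scene, warped


def cmp_edges(scene, start, T, seed, max_points=200):
    """Per-frame foreground edge sets over a CMP window of a scene."""
    return [
        tps.extract_foreground_edges(
            tps.gradient_edge_strength(scene.images[start + t]),
            scene.masks[start + t],
            frame=t,
            max_points=max_points,
            seed=seed,
        )
        for t in range(T)
    ]


def landmark_positions(scene, frame):
    lm = scene.landmarks
    sel = lm[lm["frame"] == frame]
    return sel[["x", "y"]].to_numpy(), sel["name"].tolist()
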