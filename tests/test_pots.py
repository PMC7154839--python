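import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from potkit import pots as pt
from potkit.io import Shot, Trajectory


def make_traj(tid, start, velocities, origin=(50.0, 50.0)):
    pts = np.vstack([[origin], np.asarray(origin) + np.cumsum(velocities, axis=0)])
    return Trajectory(tid, start, pts)


class TestFrameStats:
    def test_uniform_flow_has_zero_sigma(self):
        masks = np.ones((11, 8, 8), dtype=bool)
        flow = np.zeros((10, 8, 8, 2))
        flow[..., 0] = 3.0
        stats = pt.frame_stats(flow, masks, pt.PoTConfig())
        assert np.allclose(stats.median_velocity, [3.0, 0.0])
        assert np.allclose(stats.sigma, 0.0)
        assert np.allclose(stats.articulation[0], 0.0)

    def test_two_speed_population(self):
        """Half the mask still, half at speed 2: mean 1, std 1, sigma 1."""
        masks = np.ones((11, 4, 4), dtype=bool)
        flow = np.zeros((10, 4, 4, 2))
        flow[:, :2, :, 0] = 2.0
        stats = pt.frame_stats(flow, masks, pt.PoTConfig())
        assert np.allclose(stats.sigma[:-1], 1.0)

    def test_static_scene_fully_pruned(self):
        masks = np.ones((12, 4, 4), dtype=bool)
        flow = np.zeros((11, 4, 4, 2))
        stats = pt.frame_stats(flow, masks, pt.PoTConfig())
        assert stats.pruned.all()

    def test_empty_mask_marks_frame_pruned(self):
        masks = np.ones((16, 4, 4), dtype=bool)
        masks[3] = False
        flow = np.random.default_rng(0).normal(size=(15, 4, 4, 2))
        stats = pt.frame_stats(flow, masks, pt.PoTConfig())
        assert stats.pruned[0] and stats.pruned[3]  # windows covering frame 3
        assert not stats.pruned[4]


class TestScoring:
    def setup_method(self):
        self.cfg = pt.PoTConfig(n=10)
        masks = np.ones((12, 6, 6), dtype=bool)
        flow = np.zeros((11, 6, 6, 2))  # median velocity 0
        self.stats = pt.frame_stats(flow, masks, self.cfg)

    def test_closed_form_score(self):
        anchor = make_traj(0, 0, np.zeros((11, 2)))  # at the median velocity
        swing = make_traj(1, 0, np.tile([1.0, 0.0], (11, 1)))  # +1 px/frame
        scored = pt.score_candidates([anchor, swing], self.stats, 0, self.cfg)
        by_pair = {(a, s): v for v, a, s in scored}
        assert by_pair[(0, 1)] == pytest.approx(self.cfg.n * 1.0)

    def test_zero_for_identical_deviation(self):
        a = make_traj(0, 0, np.tile([1.0, 0.0], (11, 1)))
        b = make_traj(1, 0, np.tile([1.0, 0.0], (11, 1)), origin=(20, 20))
        scored = pt.score_candidates([a, b], self.stats, 0, self.cfg)
        assert all(v == pytest.approx(0.0) for v, _, _ in scored)

    def test_swapping_anchor_and_swing_negates(self):
        rng = np.random.default_rng(4)
        trajs = [make_traj(i, 0, rng.normal(size=(11, 2))) for i in range(4)]
        scored = {(a, s): v for v, a, s in pt.score_candidates(trajs, self.stats, 0, self.cfg)}
        for (a, s), v in scored.items():
            assert scored[(s, a)] == pytest.approx(-v)

    def test_fewer_than_two_live(self):
        assert pt.score_candidates([make_traj(0, 0, np.zeros((11, 2)))], self.stats, 0, self.cfg) == []


class TestSelection:
    def test_theta_p_one_keeps_all(self):
        pairs = [(float(i), i, i + 10) for i in range(8)]
        assert len(pt.select_pots(pairs, pt.PoTConfig(theta_P=1.0))) == 8

    def test_count_is_ceil(self):
        pairs = [(float(i), i, i + 10) for i in range(10)]
        kept = pt.select_pots(pairs, pt.PoTConfig(theta_P=0.15))
        assert len(kept) == 2  # ceil(1.5)
        assert [p[0] for p in kept] == [9.0, 8.0]

    def test_ties_broken_lexicographically(self):
        pairs = [(1.0, 3, 0), (1.0, 1, 2), (1.0, 1, 0), (0.5, 0, 1)]
        kept = pt.select_pots(pairs, pt.PoTConfig(theta_P=0.5))
        # brute-force oracle: sort by (-score, anchor, swing)
        expected = sorted(pairs, key=lambda p: (-p[0], p[1], p[2]))[:2]
        assert kept == expected


class TestDescriptor:
    cfg = pt.PoTConfig(n=10)

    def test_length_is_19_for_n_10(self):
        anchor = make_traj(0, 0, np.zeros((9, 2)))
        swing = make_traj(1, 0, np.tile([2.0, 0.0], (9, 1)), origin=(60, 50))
        d = pt.pot_descriptor(anchor, swing, 0, self.cfg)
        assert d.shape == (19,)

    def test_constant_velocity_closed_form(self):
        """Static anchor, swing at (2,0): every step d^k=(2,0), D=18."""
        anchor = make_traj(0, 0, np.zeros((9, 2)))
        swing = make_traj(1, 0, np.tile([2.0, 0.0], (9, 1)), origin=(60, 50))
        d = pt.pot_descriptor(anchor, swing, 0, self.cfg)
        assert d[0] == pytest.approx(0.0)  # swing is along +x from anchor
        steps = d[1:].reshape(9, 2)
        assert np.allclose(steps, [1 / 9, 0.0])

    def test_rigid_pair_discarded(self):
        anchor = make_traj(0, 0, np.tile([1.0, 1.0], (9, 1)))
        swing = make_traj(1, 0, np.tile([1.0, 1.0], (9, 1)), origin=(70, 60))
        assert pt.pot_descriptor(anchor, swing, 0, self.cfg) is None

    def test_window_not_covered_raises(self):
        anchor = make_traj(0, 0, np.zeros((5, 2)))
        swing = make_traj(1, 0, np.zeros((9, 2)), origin=(60, 50))
        with pytest.raises(ValueError, match="window"):
            pt.pot_descriptor(anchor, swing, 0, self.cfg)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_pan_invariance(self, seed):
        """A shared camera translation leaves the descriptor unchanged."""
        rng = np.random.default_rng(seed)
        va = rng.normal(size=(9, 2))
        vs = rng.normal(size=(9, 2)) + [1.5, 0]
        pan = rng.normal(size=2) * 3
        a0 = make_traj(0, 0, va)
        s0 = make_traj(1, 0, vs, origin=(70, 55))
        a1 = make_traj(0, 0, va + pan)
        s1 = make_traj(1, 0, vs + pan, origin=(70, 55))
        d0 = pt.pot_descriptor(a0, s0, 0, self.cfg)
        d1 = pt.pot_descriptor(a1, s1, 0, self.cfg)
        assert np.allclose(d0, d1, atol=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_scale_invariance_and_normalization(self, seed):
        rng = np.random.default_rng(seed)
        va = rng.normal(size=(9, 2))
        vs = rng.normal(size=(9, 2)) + [1.0, -0.5]
        a0 = make_traj(0, 0, va, origin=(40, 40))
        s0 = make_traj(1, 0, vs, origin=(70, 55))
        scale = rng.uniform(0.5, 3.0)
        a1 = Trajectory(0, 0, a0.points * scale)
        s1 = Trajectory(1, 0, s0.points * scale)
        d0 = pt.pot_descriptor(a0, s0, 0, self.cfg)
        d1 = pt.pot_descriptor(a1, s1, 0, self.cfg)
        assert np.allclose(d0, d1, atol=1e-9)
        # unit total normalized displacement
        assert np.linalg.norm(d0[1:].reshape(9, 2), axis=1).sum() == pytest.approx(1.0, abs=1e-9)


class TestExtraction:
    def test_pause_scene_yields_no_pots(self):
        from potkit import scene as sc

        scene = sc.make_scene([(sc.pause(), 20)], seed=1)
        assert pt.extract_pots(scene.to_shot(0)) == []

    def test_missing_channels_rejected(self, walk_shot):
        bare = Shot(id=1, frame_count=walk_shot.frame_count, trajectories=walk_shot.trajectories)
        with pytest.raises(ValueError, match="masks and flow"):
            pt.extract_pots(bare)

    def test_anchors_and_swings_inside_mask(self, walk_shot, walk_pots):
        by_id = {t.id: t for t in walk_shot.trajectories}
        for p in walk_pots[::500]:
            for tid in (p.anchor_id, p.swing_id):
                tr = by_id[tid]
                x, y = tr.point_at(p.start_frame)
                assert walk_shot.masks[p.start_frame][int(round(y)), int(round(x))]

    def test_normalization_of_all_emitted_pots(self, walk_pots):
        D = pt.descriptor_matrix(walk_pots)
        norms = np.linalg.norm(D[:, 1:].reshape(len(D), -1, 2), axis=2).sum(axis=1)
        assert np.abs(norms - 1).max() < 1e-9

    def test_oracle_equivalence_small_scene(self, walk_shot):
        """Vectorized extraction equals the per-operation reference path."""
        cfg = pt.PoTConfig()
        small = [t for t in pt._foreground_trajectories(walk_shot) if t.id % 9 == 0][:28]
        shot = Shot(
            id=0,
            frame_count=walk_shot.frame_count,
            trajectories=small,
            masks=walk_shot.masks,
            flow=walk_shot.flow,
        )
        stats = pt.frame_stats(shot.flow, shot.masks, cfg)
        by_id = {t.id: t for t in small}
        expected = []
        for f in range(shot.frame_count - cfg.n + 1):
            if stats.pruned[f]:
                continue
            for score, aid, sid in pt.select_pots(pt.score_candidates(small, stats, f, cfg), cfg):
                d = pt.pot_descriptor(by_id[aid], by_id[sid], f, cfg)
                if d is not None:
                    expected.append((aid, sid, f, d))
        got = pt.extract_pots(shot, cfg)
        assert len(got) == len(expected)
        for (aid, sid, f, d), p in zip(expected, got):
            assert (aid, sid, f) == (p.anchor_id, p.swing_id, p.start_frame)
            assert np.array_equal(d, p.descriptor)

    def test_swings_concentrate_on_moving_parts(self, walk_scene, walk_pots):
        """In a walking scene the selected swings lie on legs (or head)."""
        parts = walk_scene.trajectory_parts
        moving = sum(
            1
            for p in walk_pots
            if parts[p.swing_id].startswith("leg") or parts[p.swing_id] in ("head", "neck")
        )
        assert moving / len(walk_pots) >= 0.9
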