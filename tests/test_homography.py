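import numpy as np
import pytest

from potkit import homography as hg
from potkit.io import Trajectory
from potkit.mappings import Homography

T = 10


def square_mask(h=60, w=80, y0=10, y1=50, x0=10, x1=70):
    m = np.zeros((h, w), dtype=bool)
    m[y0:y1, x0:x1] = True
    return m


def random_matches(rng, H_true, n, noise=0.0, n_outliers=0):
    matches = []
    for m in range(n):
        p0 = rng.uniform(30, 200, 2)
        pts2 = np.vstack([p0, p0 + np.cumsum(rng.normal(0, 1.5, (T - 1, 2)), axis=0)])
        pts1 = H_true.apply(pts2)
        if noise:
            pts1 = pts1 + rng.normal(0, noise, (T, 2))
        if m < n_outliers:
            pts1 = pts1 + rng.uniform(30, 60, 2) * rng.choice([-1, 1], 2)
        matches.append(hg.TrajectoryMatch(m, m, 0.0, pts1, pts2))
    return matches


def grid_error(H_est, H_true):
    gy, gx = np.mgrid[30:200:20, 30:200:20]
    g = np.stack([gx.ravel(), gy.ravel()], 1).astype(float)
    return np.linalg.norm(H_est.apply(g) - H_true.apply(g), axis=1).max()


H_TRUE = Homography(np.array([[1.05, 0.02, 8.0], [-0.03, 0.98, -5.0], [1e-4, -5e-5, 1.0]]))


class TestTSDescriptor:
    def test_length_20_for_T_10(self):
        tr = Trajectory(0, 0, np.cumsum(np.ones((T, 2)), axis=0) + 20)
        d = hg.modified_ts_descriptor(tr, 0, T, square_mask())
        assert d.shape == (2 * (T - 1) + 2,)

    def test_trajectory_at_centroid_appends_zero(self):
        mask = square_mask()
        com = hg.mask_center_of_mass(mask)
        tr = Trajectory(0, 0, np.tile(com, (T, 1)))
        d = hg.modified_ts_descriptor(tr, 0, T, mask)
        assert np.allclose(d[-2:], 0.0)

    def test_offset_vector_scale_invariant(self):
        mask = square_mask()
        big = square_mask(120, 160, 20, 100, 20, 140)
        tr = Trajectory(0, 0, np.tile([20.0, 15.0], (T, 1)) + np.arange(T)[:, None])
        tr2 = Trajectory(0, 0, tr.points * 2)
        d1 = hg.modified_ts_descriptor(tr, 0, T, mask)
        d2 = hg.modified_ts_descriptor(tr2, 0, T, big)
        # pixel discretization of the doubled mask shifts com/diag by ~0.5 px
        assert np.allclose(d1[-2:], d2[-2:], atol=0.01)

    def test_empty_mask_rejected(self):
        tr = Trajectory(0, 0, np.ones((T, 2)))
        with pytest.raises(ValueError, match="empty"):
            hg.modified_ts_descriptor(tr, 0, T, np.zeros((10, 10), dtype=bool))


class TestMatching:
    def make_trajs(self, rng, n, start=0):
        out = []
        for i in range(n):
            p0 = rng.uniform(15, 45, 2)
            out.append(Trajectory(i, start, np.vstack([p0, p0 + np.cumsum(rng.normal(0, 1, (T - 1, 2)), axis=0)])))
        return out

    def test_copy_matches_twin_at_zero_distance(self):
        rng = np.random.default_rng(0)
        trajs = self.make_trajs(rng, 12)
        mask = square_mask()
        matches = hg.match_trajectories(trajs, trajs, 0, 0, T, mask, mask)
        assert all(m.id1 == m.id2 and m.distance == 0.0 for m in matches)

    def test_matches_equal_brute_force(self):
        rng = np.random.default_rng(1)
        t1 = self.make_trajs(rng, 8)
        t2 = self.make_trajs(rng, 9)
        mask = square_mask()
        matches = hg.match_trajectories(t1, t2, 0, 0, T, mask, mask)
        D1 = np.stack([hg.modified_ts_descriptor(t, 0, T, mask) for t in t1])
        D2 = np.stack([hg.modified_ts_descriptor(t, 0, T, mask) for t in t2])
        for i, m in enumerate(matches):
            brute = int(np.argmin(np.linalg.norm(D2 - D1[i], axis=1)))
            assert m.id2 == t2[brute].id

    def test_different_start_frames_never_matched(self):
        rng = np.random.default_rng(2)
        t1 = self.make_trajs(rng, 5, start=0)
        t2 = self.make_trajs(rng, 5, start=3)  # cannot span [0, T)
        mask = square_mask()
        assert hg.match_trajectories(t1, t2, 0, 0, T, mask, mask) == []


class TestFitHomography:
    boxes = [(20.0, 20.0, 220.0, 160.0)] * T

    def test_exact_recovery_no_noise(self):
        rng = np.random.default_rng(0)
        matches = random_matches(rng, H_TRUE, 20)
        al = hg.fit_homography(matches, self.boxes, self.boxes, mode="tm", seed=0)
        assert grid_error(al.homography, H_TRUE) < 1e-6
        assert al.outlier_fraction == 0.0

    def test_identity_pair(self):
        rng = np.random.default_rng(1)
        matches = random_matches(rng, Homography.identity(), 15)
        al = hg.fit_homography(matches, self.boxes, self.boxes, mode="tm", seed=0)
        assert grid_error(al.homography, Homography.identity()) < 1e-6

    @pytest.mark.parametrize("mode", ["tm", "im"])
    def test_outliers_and_noise(self, mode):
        rng = np.random.default_rng(2)
        matches = random_matches(rng, H_TRUE, 40, noise=1.0, n_outliers=8)
        al = hg.fit_homography(matches, self.boxes, self.boxes, mode=mode, seed=3)
        assert grid_error(al.homography, H_TRUE) < 2.0

    def test_tm_outlier_fraction_counts_matches(self):
        rng = np.random.default_rng(3)
        matches = random_matches(rng, H_TRUE, 20, noise=0.5, n_outliers=5)
        al = hg.fit_homography(matches, self.boxes, self.boxes, mode="tm", seed=0)
        assert al.outlier_fraction == pytest.approx(0.25, abs=0.05)

    def test_max_outlier_fraction_gate(self):
        rng = np.random.default_rng(3)
        matches = random_matches(rng, H_TRUE, 20, noise=0.5, n_outliers=5)
        assert (
            hg.fit_homography(matches, self.boxes, self.boxes, mode="tm", max_outlier_fraction=0.1, seed=0)
            is None
        )

    def test_fg_only_reduces_to_box_fit(self):
        """With no matches, the FG-regularized fit is the box-corner fit."""
        b1 = [(20.0, 30.0, 120.0, 90.0)] * T
        b2 = [(10.0, 10.0, 60.0, 40.0)] * T
        al = hg.fit_homography([], b1, b2, mode="tm", use_fg=True)
        src = hg.bbox_corners(b2[0])
        dst = hg.bbox_corners(b1[0])
        assert np.abs(al.homography.apply(src) - dst).max() < 1e-6

    def test_fg_regularization_keeps_boxes_aligned(self):
        """Matches covering one corner region only: box corners stay put."""
        rng = np.random.default_rng(4)
        matches = []
        for m in range(12):
            p0 = rng.uniform(30, 60, 2)  # all matches in one small region
            pts2 = np.vstack([p0, p0 + np.cumsum(rng.normal(0, 1, (T - 1, 2)), axis=0)])
            pts1 = H_TRUE.apply(pts2) + rng.normal(0, 1.0, (T, 2))
            matches.append(hg.TrajectoryMatch(m, m, 0.0, pts1, pts2))
        b2 = [(20.0, 20.0, 200.0, 150.0)] * T
        b1 = [tuple(np.concatenate([H_TRUE.apply([[20, 20]])[0], H_TRUE.apply([[200, 150]])[0]])) for _ in range(T)]
        al = hg.fit_homography(matches, b1, b2, mode="tm", use_fg=True, seed=0)
        err = np.abs(al.homography.apply(hg.bbox_corners(b2[0])) - hg.bbox_corners(b1[0])).max()
        assert err < 3.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        matches = random_matches(rng, H_TRUE, 30, noise=1.0, n_outliers=6)
        a = hg.fit_homography(matches, self.boxes, self.boxes, mode="tm", seed=11)
        b = hg.fit_homography(matches, self.boxes, self.boxes, mode="tm", seed=11)
        assert np.array_equal(a.homography.matrix, b.homography.matrix)
        assert a.inlier_matches == b.inlier_matches

    def test_too_few_matches(self):
        rng = np.random.default_rng(6)
        matches = random_matches(rng, H_TRUE, 3)
        assert hg.fit_homography(matches, self.boxes, self.boxes, mode="tm", seed=0) is None

    def test_normalization_convention(self):
        rng = np.random.default_rng(7)
        matches = random_matches(rng, H_TRUE, 10)
        al = hg.fit_homography(matches, self.boxes, self.boxes, mode="tm", seed=0)
        assert np.linalg.norm(al.homography.matrix) == pytest.approx(1.0)
        assert al.homography.matrix[2, 2] > 0
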