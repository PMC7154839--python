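import numpy as np
import pytest

from potkit import tps
from potkit.mappings import Homography

from conftest import cmp_edges


class TestFitTPS:
    def test_affine_pairs_fit_exactly_any_lambda(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(0, 100, (15, 2))
        U = V @ np.array([[1.1, 0.1], [-0.05, 0.95]]).T + [3.0, -2.0]
        for lam in (1e-6, 1.0, 1e4):
            f = tps.fit_tps(U, V, lam=lam)
            assert np.abs(f.apply(V) - U).max() < 1e-8
            assert f.bending_energy < 1e-16

    def test_interpolation_limit(self):
        rng = np.random.default_rng(1)
        V = rng.uniform(0, 50, (12, 2))
        U = V + rng.normal(0, 5, V.shape)
        f = tps.fit_tps(U, V, lam=1e-6)
        assert np.abs(f.apply(V) - U).max() < 1e-6

    def test_affine_limit_matches_least_squares(self):
        """On unit-scale data, lambda = 1e6 collapses to the affine LS fit."""
        rng = np.random.default_rng(2)
        V = rng.uniform(0, 1, (20, 2))
        U = V + rng.normal(0, 0.05, V.shape)
        f = tps.fit_tps(U, V, lam=1e6)
        X = np.hstack([np.ones((20, 1)), V])
        beta, *_ = np.linalg.lstsq(X, U, rcond=None)
        assert np.abs(f.apply(V) - X @ beta).max() < 1e-4

    def test_weighted_fit_respects_weights(self):
        V = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        U = V.copy()
        U[3] = [5.0, 5.0]  # one discordant pair, nearly zero weight
        f = tps.fit_tps(U, V, lam=1.0, weights=np.array([1, 1, 1, 1e-9]))
        assert np.abs(f.apply(V[:3]) - V[:3]).max() < 1e-3

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            tps.fit_tps(np.zeros((2, 2)), np.zeros((2, 2)), lam=1.0)


class TestTPSRPM:
    def test_identity_fixed_point(self):
        rng = np.random.default_rng(3)
        U = rng.uniform(10, 150, (100, 2))
        mapping, M, info = tps.tps_rpm(U, U.copy())
        scale = np.hypot(140, 140)
        assert np.linalg.norm(mapping.apply(U) - U, axis=1).mean() < 1e-3 * scale
        # soft matrix concentrates on the identity pairing
        assert (np.argmax(M, axis=1) == np.arange(len(U))).mean() > 0.95

    def test_warp_recovery_with_outliers(self):
        """TPS warp + 10% outliers recovered to < 2% of the scene scale."""
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ctrl = np.array([[20.0, 20], [140, 20], [20, 140], [140, 140], [80, 80]])
            warp = tps.fit_tps(ctrl + rng.normal(0, 8, ctrl.shape), ctrl, lam=1e-3)
            V = rng.uniform(25, 135, (150, 2))
            U = warp.apply(V)
            Uo = np.vstack([U, rng.uniform(0, 160, (15, 2))])
            Vo = np.vstack([V, rng.uniform(0, 160, (15, 2))])
            mapping, _, _ = tps.tps_rpm(Uo[rng.permutation(len(Uo))], Vo)
            land = rng.uniform(30, 130, (30, 2))
            errs.append(np.linalg.norm(mapping.apply(land) - warp.apply(land), axis=1).mean())
        scene_scale = np.hypot(160, 160)
        assert np.mean(errs) < 0.02 * scene_scale

    def test_fixed_temperature_energy_descent(self):
        """Each alternation decreases the annealed objective."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            V = rng.uniform(0, 100, (60, 2))
            U = V @ np.array([[1.05, 0.08], [-0.06, 0.97]]).T + rng.normal(0, 4, V.shape)
            es = tps.rpm_fixed_temperature_energies(U, V, temp=25.0, iterations=10)
            diffs = np.diff(es)
            assert (diffs <= 1e-9 * (1 + np.abs(es[:-1]))).all()

    def test_homography_init_composed(self):
        rng = np.random.default_rng(5)
        H = Homography.translation(20, -10)
        V = rng.uniform(20, 120, (80, 2))
        U = H.apply(V)
        mapping, _, _ = tps.tps_rpm(U, V, init_mapping=H)
        assert np.linalg.norm(mapping.apply(V) - U, axis=1).mean() < 0.5

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            tps.tps_rpm(np.empty((0, 2)), np.ones((3, 2)))


class TestEdges:
    def test_far_points_pruned_and_capped(self, head_turn_scene):
        mask = head_turn_scene.masks[0]
        strength = np.ones_like(mask, dtype=float)  # edges everywhere
        es = tps.extract_foreground_edges(strength, mask, max_points=500, seed=0)
        assert len(es.points) <= 500
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~mask)
        d = dist[es.points[:, 1].astype(int), es.points[:, 0].astype(int)]
        ys, xs = np.nonzero(mask)
        diag = np.hypot(xs.max() - xs.min(), ys.max() - ys.min())
        # surviving scores > 0.2 implies distance < ~1.61 * 0.1 * diag
        assert d.max() <= -np.log(0.2) * 0.1 * diag + 1.0

    def test_silhouette_concentration(self, head_turn_scene):
        """Mask-gradient edges land within 2 px of the true outline."""
        mask = head_turn_scene.masks[0]
        es = tps.extract_foreground_edges(
            tps.gradient_edge_strength(mask.astype(float)), mask, max_points=400, seed=0
        )
        from scipy import ndimage

        inside = ndimage.distance_transform_edt(mask)
        outside = ndimage.distance_transform_edt(~mask)
        boundary_dist = np.where(mask, inside, outside)
        d = boundary_dist[es.points[:, 1].astype(int), es.points[:, 0].astype(int)]
        assert (d <= 2.0).mean() >= 0.9

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tps.extract_foreground_edges(np.ones((5, 5)), np.zeros((5, 5), dtype=bool))

    def test_zero_flow_propagation_is_identity(self):
        es = tps.EdgePointSet(points=np.array([[3.0, 4.0], [10.0, 2.0]]), strengths=np.ones(2), frame=0)
        flow = np.zeros((3, 20, 20, 2))
        out = tps.propagate_edges(es, flow, 0, 3)
        assert np.allclose(out.points, es.points)
        assert out.source_frame == 0 and out.frame == 3

    def test_constant_flow_shifts_points(self):
        es = tps.EdgePointSet(points=np.array([[3.0, 4.0]]), strengths=np.ones(1), frame=0)
        flow = np.zeros((3, 30, 30, 2))
        flow[..., 0] = 1.0
        out = tps.propagate_edges(es, flow, 0, 3)
        assert np.allclose(out.points, [[6.0, 4.0]])

    def test_point_leaving_image_retired(self):
        es = tps.EdgePointSet(points=np.array([[18.0, 5.0], [2.0, 5.0]]), strengths=np.ones(2), frame=0)
        flow = np.zeros((3, 20, 20, 2))
        flow[..., 0] = 2.0
        out = tps.propagate_edges(es, flow, 0, 3)
        assert len(out.points) == 1  # the first point ran off the right edge

    def test_propagated_silhouette_tracks_body(self, head_turn_scene):
        """Edge points advected over 9 frames stay near the moving outline."""
        scene = head_turn_scene
        es = tps.extract_foreground_edges(
            tps.gradient_edge_strength(scene.masks[0].astype(float)), scene.masks[0], max_points=300, seed=1
        )
        track, alive = tps.propagate_track(es, scene.flow[:9], 10)
        from scipy import ndimage

        mask9 = scene.masks[9]
        inside = ndimage.distance_transform_edt(mask9)
        outside = ndimage.distance_transform_edt(~mask9)
        boundary_dist = np.where(mask9, inside, outside)
        pts = track[9][alive]
        d = boundary_dist[np.clip(pts[:, 1].round().astype(int), 0, 159), np.clip(pts[:, 0].round().astype(int), 0, 255)]
        assert np.median(d) <= 1.0


class TestTTPS:
    def test_identical_sequences_near_identity(self, head_turn_scene):
        scene = head_turn_scene
        T = 10
        edges = cmp_edges(scene, 4, T, seed=0)
        flow = scene.flow[4 : 4 + T - 1]
        al = tps.fit_ttps(edges, edges, flow, flow, anchor_frames=[0, 5, 9])
        pts = edges[0].points[::10]
        for t in (0, 5, 9):
            dev = np.linalg.norm(al.mappings[t].apply(pts) - pts, axis=1).mean()
            assert dev < 1.0

    def test_returned_candidate_is_argmin(self, warped_pair):
        orig, warped = warped_pair
        T = 10
        e1 = cmp_edges(orig, 4, T, seed=0)
        e2 = cmp_edges(warped, 4, T, seed=1)
        al = tps.fit_ttps(e1, e2, orig.flow[4:13], warped.flow[4:13], anchor_frames=[0, 3, 6, 9])
        finite = [e for e in al.candidate_energies if np.isfinite(e)]
        assert al.energy == min(finite)
        assert len(al.candidate_energies) == 4

    def test_correspondence_shared_across_frames(self, warped_pair):
        orig, warped = warped_pair
        T = 6
        e1 = cmp_edges(orig, 4, T, seed=0)
        e2 = cmp_edges(warped, 4, T, seed=1)
        al = tps.fit_ttps(e1, e2, orig.flow[4:9], warped.flow[4:9], anchor_frames=[2])
        assert al.correspondence.ndim == 2  # one shared soft matrix, by construction
        assert len(al.mappings) == T

    def test_all_candidates_skipped_raises(self):
        tiny = [tps.EdgePointSet(points=np.ones((2, 2)), strengths=np.ones(2), frame=t) for t in range(3)]
        flow = np.zeros((2, 10, 10, 2))
        with pytest.raises(ValueError, match="skipped"):
            tps.fit_ttps(tiny, tiny, flow, flow)


class TestApplyMapping:
    def test_identity_homography(self):
        from potkit.homography import HomographyAlignment

        al = HomographyAlignment(homography=Homography.identity(), mode="tm")
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(tps.apply_mapping(al, pts), pts)
        assert np.allclose(tps.apply_mapping(al, pts, direction="reverse"), pts)

    def test_homography_matches_matrix_application(self):
        from potkit.homography import HomographyAlignment

        H = Homography(np.array([[1.2, 0.0, 5.0], [0.1, 0.9, -3.0], [0.0, 0.0, 1.0]]))
        al = HomographyAlignment(homography=H, mode="tm")
        pts = np.random.default_rng(0).uniform(0, 50, (6, 2))
        assert np.allclose(tps.apply_mapping(al, pts), H.apply(pts))
        assert np.allclose(tps.apply_mapping(al, H.apply(pts), direction="reverse"), pts, atol=1e-9)

    def test_tps_forward_reverse_roundtrip(self, strong_warp):
        rng = np.random.default_rng(1)
        pts = rng.uniform(40, 120, (20, 2))
        fwd = tps.apply_mapping(strong_warp, pts, image_size=(160, 256))
        back = tps.apply_mapping(strong_warp, fwd, direction="reverse", image_size=(160, 256))
        scale = np.hypot(256, 160)
        assert np.linalg.norm(back - pts, axis=1).max() < 0.01 * scale
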