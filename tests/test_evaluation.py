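import numpy as np
import pandas as pd
import pytest

from potkit import evaluation as ev
from potkit.homography import HomographyAlignment
from potkit.mappings import Homography


def landmark_frame(points, names=None, frames=(0,), visible=True):
    rows = []
    for f in frames:
        for k, p in enumerate(points):
            name = names[k] if names else f"lm{k}"
            rows.append((f, name, p[0], p[1], visible if np.isscalar(visible) else visible[k]))
    return pd.DataFrame(rows, columns=["frame", "name", "x", "y", "visible"])


SQUARE = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])


class TestClusteringMetrics:
    def test_perfect_clustering(self):
        labels = ["a"] * 5 + ["b"] * 5
        assignments = [0] * 5 + [1] * 5
        assert ev.purity(assignments, labels) == 1.0
        assert ev.ari(assignments, labels) == pytest.approx(1.0)

    def test_singletons(self):
        labels = ["a", "a", "b", "b"]
        assignments = [0, 1, 2, 3]
        assert ev.purity(assignments, labels) == 1.0
        assert ev.ari(assignments, labels) == pytest.approx(0.0)

    def test_ari_invariant_to_label_permutation(self):
        labels = ["a", "a", "b", "b", "c", "c"]
        a1 = [0, 0, 1, 1, 2, 2]
        a2 = [5, 5, 0, 0, 9, 9]
        assert ev.ari(a1, labels) == ev.ari(a2, labels)

    def test_random_assignments_score_near_zero(self):
        labels = np.repeat(np.arange(4), 10)
        vals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            vals.append(ev.ari(rng.integers(0, 4, size=40), labels))
        assert abs(np.mean(vals)) < 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.purity([], [])
        with pytest.raises(ValueError):
            ev.ari([1], [1, 2])


class TestUniformity:
    def test_single_label(self):
        assert ev.uniformity(["walk"] * 7) == 1.0

    def test_direct_count(self):
        assert ev.uniformity(["a"] * 6 + ["b"] * 4) == pytest.approx(0.6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.uniformity([])

    def test_behavior_counts_once_per_shot(self):
        pairs = [(0, "walk"), (0, "walk"), (0, "walk"), (1, "walk"), (1, "sit")]
        counts = ev.behavior_counts(pairs)
        assert counts == {"walk": 2, "sit": 1}


class TestAlignmentError:
    frames = [0, 1]

    def identity_alignment(self):
        return HomographyAlignment(homography=Homography.identity(), mode="tm")

    def test_identity_on_identical_scenes_is_zero(self):
        lm = landmark_frame(SQUARE, frames=self.frames)
        err = ev.alignment_error(self.identity_alignment(), lm, lm, self.frames, self.frames)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_closed_form(self):
        """Mapped points offset by 0.1 x scale in both directions -> error 0.1."""
        lm1 = landmark_frame(SQUARE, frames=self.frames)
        scale = np.hypot(10, 10)
        offset = Homography.translation(0.1 * scale, 0.0)
        al = HomographyAlignment(homography=offset, mode="tm")
        # identical landmark sets: forward maps lm2+off vs lm1, reverse maps lm1-off
        err = ev.alignment_error(al, lm1, lm1, self.frames, self.frames)
        assert err == pytest.approx(0.1)

    def test_symmetric_under_sequence_swap(self):
        rng = np.random.default_rng(0)
        lm1 = landmark_frame(rng.uniform(0, 50, (6, 2)), frames=self.frames)
        lm2 = landmark_frame(rng.uniform(0, 50, (6, 2)), frames=self.frames)
        H = Homography(np.array([[1.1, 0.05, 2.0], [0.0, 0.9, -1.0], [0.0, 0.0, 1.0]]))
        fwd = HomographyAlignment(homography=H, mode="tm")
        rev = HomographyAlignment(homography=H.inverse(), mode="tm")
        e1 = ev.alignment_error(fwd, lm1, lm2, self.frames, self.frames)
        e2 = ev.alignment_error(rev, lm2, lm1, self.frames, self.frames)
        assert e1 == pytest.approx(e2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        pts1 = rng.uniform(0, 40, (5, 2))
        pts2 = rng.uniform(0, 40, (5, 2))
        lm1, lm2 = landmark_frame(pts1), landmark_frame(pts2)
        lm1s, lm2s = landmark_frame(pts1 * 3), landmark_frame(pts2 * 3)
        al = self.identity_alignment()
        S = Homography(np.diag([3.0, 3.0, 1.0]))
        als = HomographyAlignment(homography=S.compose(Homography.identity()).compose(S.inverse()), mode="tm")
        e = ev.alignment_error(al, lm1, lm2, [0], [0])
        es = ev.alignment_error(als, lm1s, lm2s, [0], [0])
        assert e == pytest.approx(es)

    def test_no_covisible_landmarks_flagged(self):
        lm1 = landmark_frame(SQUARE, names=["a", "b", "c", "d"])
        lm2 = landmark_frame(SQUARE, names=["e", "f", "g", "h"])
        with pytest.raises(ValueError, match="co-visible"):
            ev.alignment_error(self.identity_alignment(), lm1, lm2, [0], [0])


class TestVerdict:
    lm = landmark_frame(SQUARE)

    def test_threshold_rule(self):
        v = ev.verdict(0.17, self.lm, self.lm, [0], [0])
        assert v.correct
        assert not ev.verdict(0.18, self.lm, self.lm, [0], [0]).correct

    def test_low_iou_blocks_correctness(self):
        """Good error but little landmark overlap: not correct."""
        lm1 = landmark_frame(SQUARE, names=["a", "b", "c", "d"])
        lm2 = landmark_frame(SQUARE, names=["a", "x", "y", "z"])
        v = ev.verdict(0.05, lm1, lm2, [0], [0])
        assert v.landmark_iou == pytest.approx(1 / 7)
        assert not v.correct

    def test_alignable_for_exact_homography(self):
        H = Homography(np.array([[1.2, 0.1, 5.0], [-0.05, 0.95, 2.0], [0.0, 0.0, 1.0]]))
        pts = np.array([[0.0, 0], [20, 0], [20, 20], [0, 20], [10, 5]])
        lm1 = landmark_frame(pts, frames=[0, 1])
        lm2 = landmark_frame(H.inverse().apply(pts), frames=[0, 1])
        assert ev.alignable_oracle(lm1, lm2, [0, 1], [0, 1])

    def test_unrelated_scenes_not_alignable(self):
        rng = np.random.default_rng(3)
        lm1 = landmark_frame(rng.uniform(0, 50, (8, 2)), frames=[0])
        lm2 = landmark_frame(rng.uniform(0, 50, (8, 2)), frames=[0])
        assert not ev.alignable_oracle(lm1, lm2, [0], [0])


class TestPrecisionRecall:
    def test_all_returned_all_correct(self):
        curve = ev.precision_recall([0.1, 0.2, 0.3], [True, True, True], [True, True, True, True], sweep=[0.5])
        p = curve["points"][0]
        assert p["precision"] == 1.0
        assert p["recall"] == pytest.approx(3 / 4)

    def test_nothing_returned_convention(self):
        curve = ev.precision_recall([0.9], [True], [True], sweep=[0.1])
        p = curve["points"][0]
        assert p["n"] == 0 and p["precision"] == 1.0 and p["recall"] == 0.0

    def test_no_alignable_flagged(self):
        curve = ev.precision_recall([0.1], [False], [False], sweep=[0.5])
        assert np.isnan(curve["points"][0]["recall"])
        assert np.isnan(curve["average_precision"])

    def test_monotone_sweep_grows_returns(self):
        outs = [0.05, 0.15, 0.25, None]
        curve = ev.precision_recall(outs, [True, True, False, False], [True] * 4, sweep=[0.1, 0.2, 0.3])
        ns = [p["n"] for p in curve["points"]]
        assert ns == sorted(ns)
        assert curve["points"][-1]["n"] == 3  # failed fit (None) never returned
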