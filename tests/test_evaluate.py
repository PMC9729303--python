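"""Metric definitions: PE modes, OE wrap, accuracy, per-class P/R/F1."""

import math

import numpy as np
import pytest

from capstrack.evaluate import (
    MetricsReport,
    confusion_matrix,
    evaluate_tracker,
    orientation_metrics,
    position_error,
    precision_recall_f1,
    state_accuracy,
)
from capstrack.geometry import StateLabel


class TestPositionError:
    def test_identical_lists_zero_in_both_modes(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert position_error(pts, pts, "euclidean") == 0.0
        assert position_error(pts, pts, "literal") == 0.0

    def test_modes_diverge_at_equal_range(self):
        """gt (3,4) vs pred (0,5): both 5 from the origin, so the literal
        (range-difference) error vanishes while the Euclidean one does not."""
        gt, pred = np.array([[3.0, 4.0]]), np.array([[0.0, 5.0]])
        assert position_error(gt, pred, "literal") == pytest.approx(0.0)
        assert position_error(gt, pred, "euclidean") == pytest.approx(math.sqrt(10))

    def test_mean_of_euclidean_errors(self):
        gt = np.array([[0.0, 0.0], [0.0, 0.0]])
        pred = np.array([[1.0, 0.0], [0.0, 3.0]])
        assert position_error(gt, pred) == pytest.approx(2.0)

    def test_euclidean_never_below_literal(self, rng):
        """Reverse triangle inequality: | ||a|| - ||b|| | <= ||a - b||."""
        for _ in range(20):
            gt = rng.normal(size=(30, 2)) * 10
            pred = rng.normal(size=(30, 2)) * 10
            assert position_error(gt, pred, "euclidean") >= \
                position_error(gt, pred, "literal") - 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            position_error(np.zeros((2, 2)), np.zeros((3, 2)))


class TestOrientationMetrics:
    def test_exact_predictions(self):
        m = orientation_metrics([10, 20], [10, 20])
        assert m["mean"] == 0.0 and m["success_rate"] == 1.0

    def test_success_rate_threshold_count(self):
        gt = np.zeros(4)
        pred = np.array([5.0, 15.0, 9.0, 11.0])
        m = orientation_metrics(gt, pred, threshold=10.0, wrap=False)
        assert m["success_rate"] == pytest.approx(0.5)

    def test_wrap_vs_literal_at_horizontal_ambiguity(self):
        wrapped = orientation_metrics([179.0], [1.0], wrap=True)
        literal = orientation_metrics([179.0], [1.0], wrap=False)
        assert wrapped["mean"] == pytest.approx(2.0)
        assert wrapped["success_rate"] == 1.0
        assert literal["mean"] == pytest.approx(178.0)
        assert literal["success_rate"] == 0.0

    def test_population_std(self):
        m = orientation_metrics([0, 0], [3, 5], wrap=False)
        errs = np.array([3.0, 5.0])
        assert m["std"] == pytest.approx(errs.std())  # divide by N

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            orientation_metrics([], [])


class TestStateAccuracy:
    def test_all_correct(self):
        labels = ["closed", "open", "lost"]
        assert state_accuracy(labels, labels) == 1.0

    def test_two_of_three(self):
        assert state_accuracy(["closed", "open", "lost"],
                              ["closed", "open", "open"]) == pytest.approx(2 / 3)

    def test_equals_trace_over_n(self, rng):
        """Accuracy == trace(confusion)/N, cross-checked against a
        brute-force pairwise count."""
        states = [s.value for s in StateLabel]
        for _ in range(10):
            gt = rng.choice(states, size=50)
            pred = rng.choice(states, size=50)
            brute = sum(a == b for a, b in zip(gt, pred)) / 50
            m = confusion_matrix(gt, pred)
            assert state_accuracy(gt, pred) == pytest.approx(np.trace(m) / 50)
            assert state_accuracy(gt, pred) == pytest.approx(brute)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            state_accuracy(["closed"], ["ajar"])

    def test_accuracy_is_frequency_weighted_recall(self, rng):
        states = [s.value for s in StateLabel]
        gt = rng.choice(states, size=80)
        pred = rng.choice(states, size=80)
        per_class, m = precision_recall_f1(gt, pred)
        weighted = sum(row["recall"] * row["support"] for row in per_class.values()) / 80
        assert state_accuracy(gt, pred) == pytest.approx(weighted)


class TestPrecisionRecallF1:
    def test_perfect_predictions(self):
        labels = ["closed"] * 3 + ["open"] * 3 + ["lost"] * 3
        per_class, _ = precision_recall_f1(labels, labels)
        for row in per_class.values():
            assert row["precision"] == row["recall"] == row["f1"] == 1.0

    def test_hand_counted_confusion(self):
        """Constructed confusion [[8,2,0],[1,9,0],[0,0,10]] with rows/cols
        ordered open, closed, lost (one-vs-rest hand counts)."""
        gt = ["open"] * 10 + ["closed"] * 10 + ["lost"] * 10
        pred = (["open"] * 8 + ["closed"] * 2 +
                ["open"] * 1 + ["closed"] * 9 +
                ["lost"] * 10)
        per_class, m = precision_recall_f1(gt, pred)
        open_row = per_class["open"]
        assert open_row["precision"] == pytest.approx(8 / 9)
        assert open_row["recall"] == pytest.approx(0.8)
        assert open_row["f1"] == pytest.approx(16 / 19)
        assert m.sum() == 30

    def test_f1_is_harmonic_mean_everywhere(self, rng):
        states = [s.value for s in StateLabel]
        gt = rng.choice(states, size=60)
        pred = rng.choice(states, size=60)
        per_class, _ = precision_recall_f1(gt, pred)
        for row in per_class.values():
            p, r = row["precision"], row["recall"]
            expect = 2 * p * r / (p + r) if p + r else 0.0
            assert row["f1"] == pytest.approx(expect)

    def test_missing_class_gives_zero_with_warning(self, caplog):
        gt = ["closed", "closed", "open"]
        pred = ["closed", "closed", "closed"]
        with caplog.at_level("WARNING", logger="capstrack.evaluate"):
            per_class, _ = precision_recall_f1(gt, pred)
        assert per_class["lost"]["precision"] == 0.0
        assert per_class["open"]["recall"] == 0.0
        assert any("lost" in r.message or "open" in r.message for r in caplog.records)

    def test_permutation_invariance(self, rng):
        states = [s.value for s in StateLabel]
        gt = list(rng.choice(states, size=40))
        pred = list(rng.choice(states, size=40))
        perm = rng.permutation(40)
        a, ma = precision_recall_f1(gt, pred)
        b, mb = precision_recall_f1([gt[i] for i in perm], [pred[i] for i in perm])
        assert a == b and np.array_equal(ma, mb)


class _GroundTruthStub:
    """Stub models reproducing the manifest's ground truth exactly."""

    def __init__(self, manifest, kind):
        self.lookup = {}
        for rec in manifest:
            key = rec.path
            if kind == "state":
                probs = np.zeros(3)
                probs[[s for s in ("closed", "open", "lost")].index(rec.state.value)] = 1.0
                self.lookup[key] = probs
            elif rec.pose is not None:
                if kind == "orientation":
                    probs = np.zeros(180)
                    probs[int(round(rec.pose.theta)) % 180] = 1.0
                    self.lookup[key] = probs
                else:
                    self.lookup[key] = np.array(rec.pose.xy)
        self.kind = kind
        self.by_image = {}
        for rec in manifest:
            img_key = None  # filled externally
        self._manifest = manifest

    def bind_images(self, images):
        self._img_to_path = {self._hash(images[r.path]): r.path for r in self._manifest
                             if r.path in self.lookup}

    @staticmethod
    def _hash(arr):
        return arr.tobytes()

    def predict_single(self, image):
        path = self._img_to_path[self._hash(np.asarray(image))]
        return self.lookup[path]


def make_stubs(manifest):
    stubs = []
    for kind in ("state", "orientation", "centroid"):
        s = _GroundTruthStub(manifest, kind)
        s.bind_images(manifest.images)
        stubs.append(s)
    return stubs


class _ConstantState:
    def __init__(self, index):
        self.index = index

    def predict_single(self, image):
        probs = np.zeros(3)
        probs[self.index] = 1.0
        return probs


class TestEvaluateTracker:
    def test_ground_truth_stubs_give_perfect_report(self, mixed_manifest):
        state, orient, cent = make_stubs(mixed_manifest)
        report = evaluate_tracker(mixed_manifest, state, orient, cent,
                                  scale_factor=0.5)
        assert report.accuracy == 1.0
        assert report.pe_euclidean_mm == pytest.approx(0.0, abs=1e-9)
        # orientation stubs quantize to integer degrees
        assert report.oe_wrapped["mean"] < 0.5
        assert report.n_closed_misgated == 0

    def test_always_lost_stub_reports_empty_pose_metrics(self, mixed_manifest):
        _, orient, cent = make_stubs(mixed_manifest)
        report = evaluate_tracker(mixed_manifest, _ConstantState(2), orient, cent)
        assert report.n_pose_evaluated == 0
        assert report.pe_euclidean_mm is None and report.oe_wrapped is None
        assert report.n_closed_misgated == len(
            mixed_manifest.by_state(StateLabel.CLOSED))

    def test_matches_independent_per_frame_loop(self, tiny_config):
        """Report equals metrics recomputed by a brute-force loop over the
        same frames with the same stub models."""
        from capstrack.geometry import angular_distance
        from capstrack.model import hierarchical_predict
        from capstrack.synthetic import render_dataset_arrays

        counts = {StateLabel.CLOSED: 20, StateLabel.OPEN: 15, StateLabel.LOST: 15}
        _, manifest = render_dataset_arrays(tiny_config, counts, seed=55)
        manifest.images = None
        images, manifest2 = render_dataset_arrays(tiny_config, counts, seed=55)
        manifest.images = {r.path: im for r, im in zip(manifest2, images)}
        state, orient, cent = make_stubs(manifest)
        report = evaluate_tracker(manifest, state, orient, cent, scale_factor=0.5)

        correct = 0
        pe = []
        for rec in manifest:
            res = hierarchical_predict(manifest.images[rec.path], state, orient, cent, 0.5)
            correct += res.state is rec.state
            if rec.state is StateLabel.CLOSED and res.has_pose:
                pe.append(math.hypot(res.pose_mm.x - rec.pose.x * 0.5,
                                     res.pose_mm.y - rec.pose.y * 0.5))
        assert report.accuracy == pytest.approx(correct / len(manifest))
        assert report.pe_euclidean_mm == pytest.approx(np.mean(pe))
        assert report.n_pose_evaluated == len(pe)

    def test_report_json_round_trip(self, mixed_manifest):
        state, orient, cent = make_stubs(mixed_manifest)
        report = evaluate_tracker(mixed_manifest, state, orient, cent, 0.5)
        restored = MetricsReport.from_dict(__import__("json").loads(report.to_json()))
        assert restored.accuracy == report.accuracy
        assert np.array_equal(restored.confusion, report.confusion)
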