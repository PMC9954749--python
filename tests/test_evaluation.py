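import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import roc_auc_score

from conftest import make_random_prediction_records
from fabnet.evaluation import (
    ConfusionCounts,
    EvaluationError,
    PredictionRecord,
    aggregate_patch_to_image,
    confusion_counts,
    confusion_matrix,
    evaluate_predictions,
    image_level_accuracy,
    patient_level_accuracy,
    precision_recall_f1,
    roc_curve_auc,
)


def rec(rid, image, patient, true, probs):
    return PredictionRecord(rid, image, patient, true, tuple(probs))


class TestAggregation:
    def test_single_patch_passthrough(self):
        r = rec("p0", "im0", "pt0", 1, (0.3, 0.7))
        (out,) = aggregate_patch_to_image([r])
        assert out.probabilities == (0.3, 0.7)
        assert out.predicted_label == 1

    def test_hand_mean(self):
        records = [
            rec("p0", "im0", "pt0", 1, (0.2, 0.8)),
            rec("p1", "im0", "pt0", 1, (0.6, 0.4)),
        ]
        (out,) = aggregate_patch_to_image(records)
        assert out.probabilities == pytest.approx((0.4, 0.6))
        assert out.predicted_label == 1

    def test_aggregated_vectors_on_simplex(self):
        rng = np.random.default_rng(0)
        records = make_random_prediction_records(rng, n_patients=5, n_classes=3)
        for out in aggregate_patch_to_image(records):
            assert sum(out.probabilities) == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_raises(self):
        with pytest.raises(EvaluationError):
            aggregate_patch_to_image([])

    def test_soft_mean_then_argmax_contract(self):
        """Soft-mean aggregation can disagree with majority vote of argmaxes."""
        records = [
            rec("p0", "im0", "pt0", 0, (0.55, 0.45)),  # votes class 0
            rec("p1", "im0", "pt0", 0, (0.55, 0.45)),  # votes class 0
            rec("p2", "im0", "pt0", 0, (0.01, 0.99)),  # confident class 1
        ]
        (out,) = aggregate_patch_to_image(records)
        # majority vote would say 0; the soft mean says 1
        assert out.predicted_label == 1

    def test_argmax_ties_break_low_index(self):
        r = rec("p", "im", "pt", 0, (0.5, 0.5))
        assert r.predicted_label == 0


class TestAccuracies:
    def test_patient_hand_arithmetic(self):
        records = []
        # patient A: 3 of 4 correct; patient B: 1 of 2 correct
        for i, correct in enumerate([True, True, True, False]):
            p = (0.9, 0.1) if correct else (0.1, 0.9)
            records.append(rec(f"a{i}", f"a{i}", "A", 0, p))
        for i, correct in enumerate([True, False]):
            p = (0.9, 0.1) if correct else (0.1, 0.9)
            records.append(rec(f"b{i}", f"b{i}", "B", 0, p))
        acc, scores = patient_level_accuracy(records)
        by_id = {s.patient_id: s.score for s in scores}
        assert by_id["A"] == 0.75 and by_id["B"] == 0.5
        assert acc == pytest.approx(0.625)

    def test_all_correct_gives_one(self):
        records = [rec(f"r{i}", f"im{i}", f"pt{i % 2}", 1, (0.2, 0.8)) for i in range(6)]
        acc, _ = patient_level_accuracy(records)
        assert acc == 1.0
        assert image_level_accuracy(records) == 1.0

    def test_image_level_fraction(self):
        records = [
            rec(f"r{i}", f"im{i}", "pt", 0, (0.9, 0.1) if i < 9 else (0.1, 0.9))
            for i in range(10)
        ]
        assert image_level_accuracy(records) == 0.9

    def test_brute_force_oracle_equivalence(self):
        """Both accuracies equal naive recomputation on 100 random sets."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            patches = make_random_prediction_records(rng, n_patients=4, n_classes=3)
            images = aggregate_patch_to_image(patches)
            # brute force at image level
            correct = sum(
                1 for r in images if int(np.argmax(r.probabilities)) == r.true_label
            )
            assert image_level_accuracy(images) == pytest.approx(correct / len(images))
            # brute force patient mean
            pts = {}
            for r in images:
                ok = int(np.argmax(r.probabilities)) == r.true_label
                pts.setdefault(r.patient_id, []).append(ok)
            expected = np.mean([np.mean(v) for v in pts.values()])
            acc, _ = patient_level_accuracy(images)
            assert acc == pytest.approx(expected)

    def test_equal_image_counts_make_levels_coincide(self):
        """With equally many images per patient the two accuracies agree."""
        rng = np.random.default_rng(7)
        records = make_random_prediction_records(
            rng, n_patients=6, n_classes=2, images_per_patient=(3, 3), patches_per_image=(1, 1)
        )
        images = aggregate_patch_to_image(records)
        acc_p, _ = patient_level_accuracy(images)
        assert acc_p == pytest.approx(image_level_accuracy(images))

    def test_duplicating_a_patients_images_preserves_their_score(self):
        base = [rec(f"r{i}", f"im{i}", "A", 0, (0.9, 0.1)) for i in range(2)]
        base += [rec("r9", "im9", "A", 0, (0.1, 0.9))]
        _, (score,) = patient_level_accuracy(base)
        doubled = base + [
            rec(f"d{i}", f"dim{i}", "A", r.true_label, r.probabilities)
            for i, r in enumerate(base)
        ]
        _, (score2,) = patient_level_accuracy(doubled)
        assert score2.score == pytest.approx(score.score)


class TestPRF:
    def test_hand_arithmetic(self):
        p, r, f1, flag = precision_recall_f1(ConfusionCounts(tp=3, fp=1, fn=2, tn=0))
        assert p == 0.75 and r == 0.6
        assert f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert f1 == pytest.approx(0.6667, abs=1e-4)
        assert not flag

    def test_perfect_counts(self):
        p, r, f1, flag = precision_recall_f1(ConfusionCounts(tp=5, fp=0, fn=0, tn=3))
        assert (p, r, f1) == (1.0, 1.0, 1.0) and not flag

    def test_degenerate_flagged_not_raised(self):
        p, r, f1, flag = precision_recall_f1(ConfusionCounts(tp=0, fp=0, fn=0, tn=4))
        assert (p, r, f1) == (0.0, 0.0, 0.0) and flag

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        records = [rec(f"r{i}", f"im{i}", "pt", i % 3, tuple(np.eye(3)[i % 3])) for i in range(9)]
        m = confusion_matrix(records, 3)
        assert np.all(m == np.diag([3, 3, 3]))

    def test_total_equals_record_count_and_matches_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            records = make_random_prediction_records(rng, n_patients=4, n_classes=3)
            m = confusion_matrix(records, 3)
            assert m.sum() == len(records)
            truth = [r.true_label for r in records]
            pred = [r.predicted_label for r in records]
            np.testing.assert_array_equal(m, sk_confusion(truth, pred, labels=[0, 1, 2]))

    def test_unknown_label_rejected(self):
        with pytest.raises(EvaluationError):
            confusion_matrix([rec("r", "im", "pt", 5, (0.5, 0.5))], 2)

    def test_one_vs_rest_counts_consistent(self):
        rng = np.random.default_rng(5)
        records = make_random_prediction_records(rng, n_patients=5, n_classes=3)
        for c in range(3):
            counts = confusion_counts(records, c)
            assert counts.total == len(records)


class TestROC:
    def test_perfect_separation(self):
        records = [rec(f"p{i}", f"i{i}", "pt", 1, (0.1, 0.9)) for i in range(5)]
        records += [rec(f"n{i}", f"j{i}", "pt", 0, (0.8, 0.2)) for i in range(5)]
        _, auc = roc_curve_auc(records, positive_class=1)
        assert auc == 1.0

    def test_constant_scores_give_chance(self):
        records = [rec(f"p{i}", f"i{i}", "pt", i % 2, (0.5, 0.5)) for i in range(10)]
        _, auc = roc_curve_auc(records, positive_class=1)
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        records = [rec(f"p{i}", f"i{i}", "pt", 1, (0.2, 0.8)) for i in range(4)]
        with pytest.raises(EvaluationError):
            roc_curve_auc(records, positive_class=1)

    def test_mann_whitney_identity_and_sklearn(self):
        """AUC equals the rank statistic U/(n_pos*n_neg) on random data."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            truth = rng.integers(0, 2, size=n)
            if truth.min() == truth.max():
                truth[0] = 1 - truth[0]
            scores = np.round(rng.random(n), 2)  # coarse scores to exercise ties
            records = [
                rec(f"r{i}", f"im{i}", "pt", int(t), (1 - s, s))
                for i, (t, s) in enumerate(zip(truth, scores))
            ]
            _, auc = roc_curve_auc(records, positive_class=1)
            pos = scores[truth == 1]
            neg = scores[truth == 0]
            u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_curve_endpoints(self):
        rng = np.random.default_rng(1)
        records = make_random_prediction_records(rng, n_patients=5, n_classes=2)
        curve, _ = roc_curve_auc(records, positive_class=0)
        np.testing.assert_allclose(curve[0], [0.0, 0.0])
        np.testing.assert_allclose(curve[-1], [1.0, 1.0])


class TestFullReport:
    def test_metrics_bounded_and_complete(self):
        rng = np.random.default_rng(2)
        patches = make_random_prediction_records(rng, n_patients=6, n_classes=3)
        report = evaluate_predictions(patches, n_classes=3)
        for key in ("patch_level_accuracy", "image_level_accuracy", "patient_level_accuracy"):
            assert 0.0 <= report[key] <= 1.0
        for cls, stats in report["per_class"].items():
            for metric in ("precision", "recall", "f1"):
                assert 0.0 <= stats[metric] <= 1.0
        assert len(report["confusion_matrix"]) == 3
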