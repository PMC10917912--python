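"""Evaluation stack versus brute-force, rank-statistic and sklearn oracles."""

import numpy as np
import pytest

from wfpn.metrics import (
    ConfusionMatrix,
    PredictionRecord,
    confusion_matrix,
    full_report,
    prf_accuracy,
    roc_auc,
    roc_curve_binary,
)


def random_records(rng, n=30, k=4):
    truth = rng.integers(0, k, n)
    scores = rng.normal(size=(n, k))
    return [PredictionRecord.from_scores(scores[i], truth[i]) for i in range(n)]


class TestConfusionMatrix:
    def test_all_correct_two_classes(self):
        records = [PredictionRecord(np.eye(2)[c], c, c) for c in (0, 1) for _ in range(50)]
        cm = confusion_matrix(records, 2)
        np.testing.assert_array_equal(cm.counts, np.diag([50, 50]))

    def test_single_record_lands_in_true_row_predicted_column(self):
        cm = confusion_matrix([PredictionRecord(np.zeros(4), predicted=0, true=2)], 4)
        expected = np.zeros((4, 4), dtype=int)
        expected[2, 0] = 1
        np.testing.assert_array_equal(cm.counts, expected)

    def test_matches_nested_loop_counting(self):
        rng = np.random.default_rng(5)
        records = random_records(rng)
        cm = confusion_matrix(records, 4)
        oracle = np.zeros((4, 4), dtype=int)
        for r in records:
            oracle[r.true, r.predicted] += 1
        np.testing.assert_array_equal(cm.counts, oracle)
        assert cm.total == len(records)

    def test_row_and_column_sums_decompose_into_tp_fp_fn(self):
        rng = np.random.default_rng(6)
        cm = confusion_matrix(random_records(rng), 4)
        for c in range(4):
            tp, fp, fn, tn = cm.one_vs_rest(c)
            assert tp + fn == cm.counts[c, :].sum()
            assert tp + fp == cm.counts[:, c].sum()
            assert tp + fp + fn + tn == cm.total

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            confusion_matrix([PredictionRecord(np.zeros(4), 0, 7)], 4)


class TestPrfAccuracy:
    def test_direct_substitution_example(self):
        # one-vs-rest TP=8, FP=2, FN=2 -> P = R = F1 = 0.8
        counts = np.array([[8, 1, 1], [1, 5, 0], [1, 0, 5]])
        report = prf_accuracy(ConfusionMatrix(counts))
        assert report.per_class_precision[0] == pytest.approx(0.8)
        assert report.per_class_recall[0] == pytest.approx(0.8)
        assert report.per_class_f1[0] == pytest.approx(0.8)

    def test_macro_f1_is_plain_mean(self):
        # this table realises per-class F1 of exactly (1.0, 0.5, 0.75)
        counts = np.array([[2, 0, 0], [0, 1, 1], [0, 1, 3]])
        report = prf_accuracy(ConfusionMatrix(counts))
        assert report.per_class_f1 == pytest.approx([1.0, 0.5, 0.75])
        assert report.macro_f1 == pytest.approx(0.75)

    def test_matches_per_cell_hand_computation(self):
        rng = np.random.default_rng(7)
        cm = confusion_matrix(random_records(rng, n=60), 4)
        report = prf_accuracy(cm)
        total = cm.counts.sum()
        f1s = []
        for c in range(4):
            tp = cm.counts[c, c]
            fp = cm.counts[:, c].sum() - tp
            fn = cm.counts[c, :].sum() - tp
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f = 2 * p * r / (p + r) if p + r else 0.0
            f1s.append(f)
            assert report.per_class_precision[c] == pytest.approx(p, abs=1e-12)
            assert report.per_class_recall[c] == pytest.approx(r, abs=1e-12)
        assert report.accuracy == pytest.approx(np.trace(cm.counts) / total, abs=1e-12)
        assert report.macro_f1 == pytest.approx(np.mean(f1s), abs=1e-12)

    def test_zero_denominators_report_zero(self):
        # class 1 never predicted and never true beyond row
        counts = np.array([[5, 0], [3, 0]])
        report = prf_accuracy(ConfusionMatrix(counts))
        assert report.per_class_precision[1] == 0.0
        assert report.per_class_recall[1] == 0.0
        assert report.per_class_f1[1] == 0.0


class TestRocAuc:
    def test_perfect_separation_gives_unit_auc(self):
        records = [
            PredictionRecord.from_scores([1.0 - 0.1 * i if c == 0 else 0.0, 0.0, 0.0, 0.0], c)
            for i, c in enumerate([0, 0, 0])
        ] + [
            PredictionRecord.from_scores([-1.0 - 0.1 * i, 0.5, 0.2, 0.2], c)
            for i, c in enumerate([1, 2, 3, 1, 2, 3])
        ]
        report = roc_auc(records, 4)
        assert report.per_class_auc["stage1"] == pytest.approx(1.0)

    def test_constant_scores_give_half_auc(self):
        records = [PredictionRecord.from_scores([0.3, 0.3, 0.3, 0.3], c) for c in [0, 1, 2, 3] * 5]
        report = roc_auc(records, 4)
        for lab, auc in report.per_class_auc.items():
            assert auc == pytest.approx(0.5)

    def test_binary_auc_equals_mann_whitney_statistic(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=20)
        truth = rng.integers(0, 2, 20)
        truth[:2] = [0, 1]  # both classes present
        pts = roc_curve_binary(scores, truth == 1)
        auc = np.trapezoid([p[1] for p in pts], [p[0] for p in pts])
        pos = scores[truth == 1]
        neg = scores[truth == 0]
        # U statistic: fraction of (pos, neg) pairs ranked correctly, ties half
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_absent_class_excluded_from_macro(self):
        records = [PredictionRecord.from_scores(np.eye(4)[c], c) for c in [0, 1, 2] * 4]
        report = roc_auc(records, 4)
        assert "stage4" not in report.per_class_auc
        assert report.macro_auc == pytest.approx(
            np.mean([report.per_class_auc[f"stage{i}"] for i in (1, 2, 3)])
        )


class TestOracleEquivalenceSweep:
    @pytest.mark.parametrize("seed", range(100))
    def test_full_stack_agrees_with_sklearn(self, seed):
        from sklearn.metrics import confusion_matrix as sk_cm
        from sklearn.metrics import f1_score, roc_auc_score

        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 60))
        truth = rng.integers(0, 4, n)
        truth[:4] = [0, 1, 2, 3]  # every class present
        scores = rng.normal(size=(n, 4))
        records = [PredictionRecord.from_scores(scores[i], truth[i]) for i in range(n)]
        report, cm = full_report(records, 4)
        pred = [r.predicted for r in records]
        np.testing.assert_array_equal(cm.counts, sk_cm(truth, pred, labels=range(4)))
        assert report.macro_f1 == pytest.approx(
            f1_score(truth, pred, average="macro", zero_division=0), abs=1e-12
        )
        assert report.accuracy == pytest.approx(np.mean(np.array(pred) == truth), abs=1e-12)
        # one-vs-rest AUC per class against sklearn's binary implementation
        aucs = []
        for c, lab in enumerate(report.class_labels):
            sk_auc = roc_auc_score(truth == c, scores[:, c])
            assert report.per_class_auc[lab] == pytest.approx(sk_auc, abs=1e-10)
            aucs.append(sk_auc)
        assert report.macro_auc == pytest.approx(np.mean(aucs), abs=1e-10)


class TestInvariances:
    def test_record_order_is_irrelevant(self):
        rng = np.random.default_rng(9)
        records = random_records(rng, n=40)
        report_a, cm_a = full_report(records, 4)
        rng.shuffle(records)
        report_b, cm_b = full_report(records, 4)
        np.testing.assert_array_equal(cm_a.counts, cm_b.counts)
        assert report_a.to_dict() == report_b.to_dict()

    def test_binary_case_reduces_to_textbook_formulas(self):
        cm = ConfusionMatrix(np.array([[40, 10], [5, 45]]), ["neg", "pos"])
        report = prf_accuracy(cm)
        tp, fn, fp, tn = 45, 5, 10, 40
        assert report.per_class_precision[1] == pytest.approx(tp / (tp + fp))
        assert report.per_class_recall[1] == pytest.approx(tp / (tp + fn))
        assert report.accuracy == pytest.approx((tp + tn) / 100)

    def test_row_normalisation(self):
        cm = ConfusionMatrix(np.array([[3, 1], [0, 0]]))
        norm = cm.normalized()
        np.testing.assert_allclose(norm[0], [0.75, 0.25])
        np.testing.assert_array_equal(norm[1], [0.0, 0.0])
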