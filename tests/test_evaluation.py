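"""Confusion/metrics arithmetic and rank-based one-vs-rest AUC."""

import numpy as np
import pytest

from suturevision.evaluation import (
    ConfusionMatrix,
    accuracy,
    class_metrics,
    confusion,
    evaluate_predictions,
    f1_score,
    roc_auc,
    roc_curve_points,
)

# printed evaluation-table rows used as arithmetic worked examples:
# (precision, recall, f1), (auc)
TABLE_ROWS = [
    (0.5926, 0.8000, 0.6809, 0.9106),
    (0.4348, 0.5000, 0.4651, 0.6825),
    (0.6923, 0.4500, 0.5455, 0.6581),
    (0.6000, 0.6000, 0.6000, 0.7262),
    (0.5882, 0.5000, 0.5405, 0.7887),
]


class TestConfusion:
    def test_perfect_predictions_fill_diagonal(self):
        t = np.repeat(np.arange(5), 20)
        cm = confusion(t, t)
        np.testing.assert_array_equal(cm.counts, np.eye(5, dtype=int) * 20)
        assert cm.total == 100

    def test_single_predicted_class_fills_one_column(self):
        t = np.repeat(np.arange(5), 4)
        cm = confusion(t, np.zeros_like(t))
        assert cm.counts[:, 0].sum() == 20
        assert cm.counts[:, 1:].sum() == 0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 5, size=100)
        p = rng.integers(0, 5, size=100)
        cm = confusion(t, p)
        for i in range(5):
            for j in range(5):
                assert cm.counts[i, j] == sum(
                    1 for a, b in zip(t, p) if a == i and b == j
                )

    def test_length_mismatch_and_bad_labels(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([0, 1], [0])
        with pytest.raises(ValueError, match="0..4"):
            confusion([0, 9], [0, 1])


class TestClassMetrics:
    def test_against_per_sample_counting_oracle(self):
        rng = np.random.default_rng(1)
        t = rng.integers(0, 5, size=80)
        p = rng.integers(0, 5, size=80)
        rep = class_metrics(confusion(t, p))
        for x in range(5):
            tp = int(((t == x) & (p == x)).sum())
            fp = int(((t != x) & (p == x)).sum())
            fn = int(((t == x) & (p != x)).sum())
            row = rep.per_class.iloc[x]
            assert (row.TP, row.FP, row.FN) == (tp, fp, fn)
            assert row.TN == 80 - tp - fp - fn
            if tp + fp:
                assert row.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert row.recall == pytest.approx(tp / (tp + fn))

    @pytest.mark.parametrize("p,r,f1,_auc", TABLE_ROWS)
    def test_f1_reproduces_printed_rows(self, p, r, f1, _auc):
        assert f1_score(p, r) == pytest.approx(f1, abs=5e-5)

    def test_f1_of_equal_p_and_r_is_that_value(self):
        for v in (0.1, 0.6, 0.97):
            assert f1_score(v, v) == pytest.approx(v)
        assert f1_score(0.0, 0.0) == 0.0

    def test_micro_recall_equals_accuracy(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 5, size=200)
        p = rng.integers(0, 5, size=200)
        rep = class_metrics(confusion(t, p))
        micro = rep.per_class.TP.sum() / rep.per_class.support.sum()
        assert micro == pytest.approx(rep.accuracy)

    def test_per_class_acc_sum_is_literal_summation(self):
        cm = confusion([0, 0, 1, 2], [0, 1, 1, 2])
        rep = class_metrics(cm)
        expected = sum(
            (rep.per_class.TP[x] + rep.per_class.TN[x]) / 4 for x in range(5)
        )
        assert rep.per_class_acc_sum == pytest.approx(expected)
        assert rep.accuracy == pytest.approx(3 / 4)


class TestAccuracy:
    def test_degenerate_matrices(self):
        diag = ConfusionMatrix(np.eye(5, dtype=int) * 7)
        assert accuracy(diag) == 1.0
        off = ConfusionMatrix(np.ones((5, 5), dtype=int) - np.eye(5, dtype=int))
        assert accuracy(off) == 0.0
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(np.zeros((5, 5), dtype=int)))

    def test_trace_over_total_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 9, size=(5, 5))
        cm = ConfusionMatrix(counts)
        assert accuracy(cm) == pytest.approx(np.trace(counts) / counts.sum())


def _scores_for(t, sep, rng):
    """Softmax-like rows favouring the true class by margin ``sep``."""
    n = len(t)
    raw = rng.uniform(0.1, 1.0, size=(n, 5))
    raw[np.arange(n), t] += sep
    return raw / raw.sum(axis=1, keepdims=True)


class TestRocAuc:
    def test_perfect_separation_gives_unit_aucs(self):
        t = np.repeat(np.arange(5), 10)
        scores = np.full((50, 5), 0.025)
        scores[np.arange(50), t] = 0.9
        aucs, avg = roc_auc(scores, t)
        assert all(a == 1.0 for a in aucs.values())
        assert avg == 1.0

    def test_printed_aucs_average(self):
        aucs = [row[3] for row in TABLE_ROWS]
        assert np.mean(aucs) == pytest.approx(0.7532, abs=5e-5)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(4)
        t = rng.integers(0, 5, size=2000)
        aucs, avg = roc_auc(_scores_for(t, 0.0, rng), t)
        # SE of AUC ~ 1/sqrt(n_pos) scale; 3 SE band around chance
        assert abs(avg - 0.5) < 3 * 0.5 / np.sqrt(350)

    def test_agrees_with_sklearn_cross_check(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        t = rng.integers(0, 5, size=150)
        scores = _scores_for(t, 0.4, rng)
        aucs, _ = roc_auc(scores, t)
        for x in range(5):
            ref = sklearn_metrics.roc_auc_score((t == x).astype(int), scores[:, x])
            assert aucs[x] == pytest.approx(ref, abs=1e-12)

    def test_rank_auc_equals_trapezoidal_roc_area(self):
        rng = np.random.default_rng(6)
        t = rng.integers(0, 5, size=120)
        scores = _scores_for(t, 0.3, rng)
        aucs, _ = roc_auc(scores, t)
        for x in range(5):
            pts = roc_curve_points(scores, t, x)
            area = np.trapezoid(pts["tpr"], pts["fpr"])
            assert aucs[x] == pytest.approx(area, abs=1e-12)

    def test_absent_class_excluded_with_warning(self):
        t = np.repeat([0, 1, 2, 3], 5)  # class 4 never occurs
        rng = np.random.default_rng(7)
        scores = _scores_for(t, 0.5, rng)
        with pytest.warns(UserWarning, match="class 4"):
            aucs, avg = roc_auc(scores, t)
        assert 4 not in aucs
        assert avg == pytest.approx(np.mean([aucs[x] for x in range(4)]))

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            roc_auc(np.ones((4, 5)), [0, 1, 2, 3])


class TestEvaluatePredictions:
    def test_full_report_shape(self):
        rng = np.random.default_rng(8)
        t = np.repeat(np.arange(5), 20)
        scores = _scores_for(t, 0.5, rng)
        rep = evaluate_predictions(scores, t)
        assert rep.average_auc is not None and 0.5 < rep.average_auc <= 1.0
        table = rep.to_table()
        assert len(table) == 5
        assert "label (age range)" in table.columns
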