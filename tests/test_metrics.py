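"""Evaluation-metric formulas, ROC/AUC behavior, and comparison arithmetic."""

import numpy as np
import pytest

from psiscan.metrics import (
    PUBLISHED_INDEPENDENT,
    ConfusionCounts,
    comparison_table,
    compute_metrics,
    confusion_from_predictions,
    counts_from_rates,
    relative_improvement,
    roc_auc,
)


class TestComputeMetrics:
    def test_sc200_style_counts(self):
        """Balanced 200-sample set with SN 80% / SP 73%."""
        rep = compute_metrics(ConfusionCounts(tp=80, tn=73, fp=27, fn=20))
        assert round(rep.sensitivity, 3) == 0.800
        assert round(rep.specificity, 3) == 0.730
        assert round(rep.accuracy, 3) == 0.765
        assert round(rep.mcc, 2) == 0.53

    def test_no_association_gives_zero_mcc(self):
        assert compute_metrics(ConfusionCounts(25, 25, 25, 25)).mcc == 0

    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert rep.sensitivity == rep.specificity == rep.accuracy == rep.mcc == 1

    def test_zero_denominators_flagged_not_nan(self):
        rep = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert rep.sensitivity is None and rep.mcc is None
        assert rep.specificity == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)

    def test_brute_force_recount_oracle(self):
        """compute_metrics agrees with metrics recomputed naively from the
        expanded (label, prediction) pairs on 1,000 random tables."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, 4))
            if tp + tn + fp + fn == 0:
                continue
            labels = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            preds = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            c = confusion_from_predictions(labels, preds)
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
            rep = compute_metrics(c)
            labels, preds = np.array(labels), np.array(preds)
            assert rep.accuracy == pytest.approx(np.mean(labels == preds))
            if tp + fn:
                assert rep.sensitivity == pytest.approx(
                    np.mean(preds[labels == 1] == 1)
                )
            if tn + fp:
                assert rep.specificity == pytest.approx(
                    np.mean(preds[labels == 0] == 0)
                )
            if rep.mcc is not None:
                assert rep.mcc == pytest.approx(np.corrcoef(labels, preds)[0, 1])

    def test_balanced_accuracy_identity(self):
        """For balanced sets, AC == (SN + SP) / 2 exactly."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(1, 50))
            tp = int(rng.integers(0, n + 1))
            tn = int(rng.integers(0, n + 1))
            rep = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=n - tn, fn=n - tp))
            assert rep.accuracy == pytest.approx((rep.sensitivity + rep.specificity) / 2)

    def test_counts_from_rates_reconstruction(self):
        c = counts_from_rates(73.0, 75.0, 100, 100)
        assert (c.tp, c.tn, c.fp, c.fn) == (73, 75, 25, 27)
        rep = compute_metrics(c)
        assert round(rep.accuracy, 3) == 0.740 and round(rep.mcc, 2) == 0.48


class TestRocAuc:
    def test_perfectly_separated(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_perfectly_reversed(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert auc == 0.0

    def test_exchangeable_scores_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.random(2000)
        labels = np.repeat([0, 1], 1000)
        auc, _ = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(5 * scores) - 1, labels)
        assert a1 == pytest.approx(a2)


class TestRelativeImprovement:
    @pytest.mark.parametrize(
        "new,old,expected",
        [
            (85.61, 71.18, 20.27),  # HS_990 sensitivity gain
            (80.00, 68.76, 16.34),  # SC_200 sensitivity gain
            (50.0, 50.0, 0.0),
        ],
    )
    def test_published_arithmetic(self, new, old, expected):
        assert relative_improvement(new, old) == expected

    def test_zero_baseline_undefined(self):
        assert relative_improvement(5.0, 0.0) is None


class TestComparisonTable:
    def test_improvements_over_baseline(self):
        ours = {
            "ours(merged-seq)": compute_metrics(ConfusionCounts(tp=80, tn=73, fp=27, fn=20))
        }
        table = comparison_table(
            ours, PUBLISHED_INDEPENDENT["SC_200"], baseline="iPseU-CNN"
        )
        row = table.loc["ours(merged-seq)"]
        assert row["ΔSN(%) vs iPseU-CNN"] == 16.34
        assert row["ΔAC(%) vs iPseU-CNN"] == 4.08
        assert row["ΔMCC vs iPseU-CNN"] == 12.76

    def test_without_published_rows(self):
        ours = {"ours": compute_metrics(ConfusionCounts(10, 10, 0, 0))}
        table = comparison_table(ours)
        assert list(table.index) == ["ours"] and table.loc["ours", "AC(%)"] == 100.0

    def test_missing_metrics_are_na(self):
        ours = {"ours": compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))}
        table = comparison_table(ours)
        assert table.loc["ours", "SN(%)"] is None or np.isnan(table.loc["ours", "SN(%)"])
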