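"""Evaluation metrics: sensitivity, specificity, accuracy, MCC, ROC/AUC,
and the relative-improvement arithmetic used for predictor comparisons.

Metrics with a zero denominator are surfaced as explicit ``None`` flags
rather than NaN so that degenerate cross-validation folds cannot silently
poison averaged scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "compute_metrics",
    "confusion_from_predictions",
    "counts_from_rates",
    "roc_auc",
    "relative_improvement",
    "comparison_table",
    "PUBLISHED_BENCHMARK",
    "PUBLISHED_INDEPENDENT",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity/specificity/accuracy as proportions in [0,1]; MCC in
    [-1,1]; any metric whose denominator is zero is ``None``."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float
    mcc: float | None
    auc: float | None = None

    def as_percent_row(self) -> dict[str, float | None]:
        """AC/SN/SP as percentages (2 dp), MCC as a value (2 dp) — table layout."""
        pct = lambda x: None if x is None else round(100 * x, 2)
        return {
            "AC(%)": pct(self.accuracy),
            "SN(%)": pct(self.sensitivity),
            "SP(%)": pct(self.specificity),
            "MCC": None if self.mcc is None else round(self.mcc, 2),
        }


def compute_metrics(c: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
    (TP+TN)/total, and the Matthews correlation coefficient

        MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    sn = c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    sp = c.tn / (c.tn + c.fp) if c.tn + c.fp else None
    ac = (c.tp + c.tn) / c.total
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else None
    return MetricsReport(sn, sp, ac, mcc, auc)


def confusion_from_predictions(labels, predictions) -> ConfusionCounts:
    """Count a confusion table from paired true/predicted binary labels."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must align")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def counts_from_rates(sn_pct: float, sp_pct: float, n_pos: int, n_neg: int) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed SN/SP percentages
    and known class sizes (e.g. a balanced 200-sample independent set)."""
    tp = round(sn_pct / 100 * n_pos)
    tn = round(sp_pct / 100 * n_neg)
    return ConfusionCounts(tp=tp, tn=tn, fp=n_neg - tn, fn=n_pos - tp)


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC plus the ROC point list for positive-class scores.

    Requires at least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return float(_sk_auc(fpr, tpr)), points


def relative_improvement(new: float, old: float) -> float | None:
    """Percentage change 100*(new-old)/old, reported to 2 dp; None if old==0.

    The value is truncated toward zero at the second decimal — the
    convention the comparative tables this mirrors were computed with
    (e.g. 11.24/68.76 -> 16.34, 0.06/0.47 -> 12.76).
    """
    if old == 0:
        return None
    return math.trunc(10000.0 * (new - old) / old) / 100.0


#: Published predictor results on the benchmark sets (treated as constants).
#: dataset -> predictor -> {AC(%), SN(%), SP(%), MCC}
PUBLISHED_BENCHMARK: dict[str, dict[str, dict[str, float]]] = {
    "SC_628": {
        "iRNA-PseU": {"AC(%)": 64.49, "SN(%)": 64.65, "SP(%)": 64.33, "MCC": 0.29},
        "PseUI": {"AC(%)": 65.13, "SN(%)": 62.74, "SP(%)": 67.52, "MCC": 0.30},
        "iPseU-CNN": {"AC(%)": 68.15, "SN(%)": 66.84, "SP(%)": 69.45, "MCC": 0.37},
        "XGboost": {"AC(%)": 68.15, "SN(%)": 66.84, "SP(%)": 69.45, "MCC": 0.37},
        "iPseU-Layer": {"AC(%)": 89.34, "SN(%)": 84.68, "SP(%)": 93.76, "MCC": 0.79},
    },
    "HS_990": {
        "iRNA-PseU": {"AC(%)": 60.40, "SN(%)": 61.01, "SP(%)": 59.80, "MCC": 0.21},
        "PseUI": {"AC(%)": 64.24, "SN(%)": 64.85, "SP(%)": 63.64, "MCC": 0.28},
        "iPseU-CNN": {"AC(%)": 66.68, "SN(%)": 65.0, "SP(%)": 68.78, "MCC": 0.34},
        "XGboost": {"AC(%)": 65.44, "SN(%)": 63.64, "SP(%)": 67.24, "MCC": 0.31},
        "iPseU-Layer": {"AC(%)": 79.70, "SN(%)": 71.18, "SP(%)": 88.22, "MCC": 0.60},
    },
    "MM_944": {
        "iRNA-PseU": {"AC(%)": 69.07, "SN(%)": 73.31, "SP(%)": 64.83, "MCC": 0.38},
        "PseUI": {"AC(%)": 70.44, "SN(%)": 74.58, "SP(%)": 66.31, "MCC": 0.41},
        "iPseU-CNN": {"AC(%)": 71.81, "SN(%)": 74.79, "SP(%)": 69.11, "MCC": 0.44},
        "XGboost": {"AC(%)": 72.03, "SN(%)": 76.48, "SP(%)": 67.57, "MCC": 0.45},
        "iPseU-Layer": {"AC(%)": 80.08, "SN(%)": 77.92, "SP(%)": 81.82, "MCC": 0.60},
    },
}

#: Published predictor results on the independent sets (constants).
PUBLISHED_INDEPENDENT: dict[str, dict[str, dict[str, float]]] = {
    "SC_200": {
        "iRNA-PseU": {"AC(%)": 60.00, "SN(%)": 63.00, "SP(%)": 57.00, "MCC": 0.20},
        "PseUI": {"AC(%)": 68.50, "SN(%)": 65.00, "SP(%)": 72.00, "MCC": 0.37},
        "iPseU-CNN": {"AC(%)": 73.50, "SN(%)": 68.76, "SP(%)": 77.42, "MCC": 0.47},
        "iPseU-Layer": {"AC(%)": 72.50, "SN(%)": 68.00, "SP(%)": 77.00, "MCC": 0.45},
    },
    "HS_200": {
        "iRNA-PseU": {"AC(%)": 61.50, "SN(%)": 58.00, "SP(%)": 65.00, "MCC": 0.23},
        "PseUI": {"AC(%)": 65.50, "SN(%)": 63.00, "SP(%)": 68.00, "MCC": 0.31},
        "iPseU-CNN": {"AC(%)": 69.00, "SN(%)": 77.72, "SP(%)": 60.81, "MCC": 0.40},
        "iPseU-Layer": {"AC(%)": 71.00, "SN(%)": 63.00, "SP(%)": 79.00, "MCC": 0.43},
    },
}


def comparison_table(
    ours: dict[str, MetricsReport],
    published: dict[str, dict[str, float]] | None = None,
    baseline: str | None = None,
) -> pd.DataFrame:
    """Render a predictor-comparison table, optionally with relative
    improvements of each of our rows over one published baseline predictor.

    ``ours`` maps row names (e.g. ``"ours(merged-seq)"``) to reports;
    ``published`` maps predictor names to metric dicts (constants).  Missing
    metrics come out as NA cells.
    """
    rows: dict[str, dict[str, float | None]] = {}
    for name, vals in (published or {}).items():
        rows[name] = dict(vals)
    for name, report in ours.items():
        rows[name] = report.as_percent_row()
    table = pd.DataFrame.from_dict(rows, orient="index")
    if baseline is not None and published and baseline in published:
        base = published[baseline]
        for name, report in ours.items():
            mine = report.as_percent_row()
            for metric in ("AC(%)", "SN(%)", "SP(%)", "MCC"):
                col = f"Δ{metric} vs {baseline}"
                if mine.get(metric) is not None and base.get(metric) is not None:
                    table.loc[name, col] = relative_improvement(mine[metric], base[metric])
    return table
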