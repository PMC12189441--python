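"""Classification metrics, one-way ANOVA and compression-rate arithmetic.

Accuracy, precision and recall come straight from the confusion counts;
AUC is the area under the ROC curve (threshold sweep, trapezoid rule),
which equals the rank statistic P(score+ > score-) + 0.5 P(tie). Precision
or recall with a zero denominator is reported as an explicit undefined
flag (None), never silently as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "MetricsReport", "confusion_and_metrics", "auc", "compression_rate",
    "one_way_anova", "anova_from_sums_of_squares", "report_json",
    "distillation_report_table",
]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float | None
    recall: float | None
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        fmt = lambda v: "undefined" if v is None else f"{100 * v:.2f}%"
        return (f"n={self.n}  TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}\n"
                f"accuracy={fmt(self.accuracy)}  precision={fmt(self.precision)}  "
                f"recall={fmt(self.recall)}  AUC={fmt(self.auc)}")


def confusion_and_metrics(y_true, y_pred) -> MetricsReport:
    """Confusion counts and accuracy/precision/recall from binary vectors."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    accuracy = (tp + tn) / yt.size
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                         precision=precision, recall=recall)


def auc(y_true, scores) -> float:
    """Area under the ROC curve by threshold sweep with the trapezoid rule."""
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ValueError("y_true and scores must be equal-length")
    if len(np.unique(yt)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    fpr, tpr, _ = roc_curve(yt, s)
    return float(np.trapezoid(tpr, fpr))


def compression_rate(teacher_param_count: float, student_param_count: float) -> float:
    """Parameter reduction in percent: 100 * (1 - student/teacher), rounded
    to two decimals. A student larger than its teacher yields a negative
    rate (reported, not rejected)."""
    if teacher_param_count <= 0 or student_param_count <= 0:
        raise ValueError("parameter counts must be positive")
    rate = 100.0 * (1.0 - student_param_count / teacher_param_count)
    if rate < 0:
        import warnings
        warnings.warn("student has more parameters than teacher; "
                      "compression rate is negative")
    return round(rate, 2)


def one_way_anova(groups) -> dict:
    """Standard one-way ANOVA decomposition over >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    if ss_within == 0.0:
        raise ValueError("zero within-group variance everywhere: F degenerate")
    return anova_from_sums_of_squares(ss_between, ss_within, df1, df2)


def anova_from_sums_of_squares(ss_between: float, ss_within: float,
                               df1: int, df2: int) -> dict:
    """F and p reconstructed from the sums of squares and their degrees of
    freedom (the path used to audit a printed ANOVA table)."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be positive")
    if ss_within <= 0:
        raise ValueError("within-group sum of squares must be positive")
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df1, df2))
    return {"ss_between": ss_between, "ss_within": ss_within,
            "df1": df1, "df2": df2, "F": f, "p": p}


def distillation_report_table(deltas_pct: list[float]) -> dict:
    """Aggregate a list of per-pair accuracy deltas (percentage points)."""
    if len(deltas_pct) == 0:
        return {"n_pairs": 0, "mean_delta_pct": None, "note": "no runs"}
    return {"n_pairs": len(deltas_pct),
            "mean_delta_pct": round(float(np.mean(deltas_pct)), 2),
            "max_delta_pct": round(float(np.max(deltas_pct)), 2)}


def report_json(artifacts: dict, path: str | None = None) -> str:
    """Serialize run artifacts deterministically; round-trips via json."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    text = json.dumps(artifacts, indent=2, sort_keys=True, default=default)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
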