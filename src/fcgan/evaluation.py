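"""Confusion-matrix metrics, ROC/AUC and multi-group report tables.

ASD is the positive class throughout: sensitivity (= recall) is the true
positive rate on ASD, specificity the true negative rate on HC. Metrics
whose denominator is zero are reported as ``None`` with a flag rather than
NaN. Aggregation across folds or sites recomputes metrics from the *summed*
confusion counts — pooled accuracy is the count-weighted value, which in
general differs from the mean of per-group percentages.

Recall is emitted as a separate column even though it is computed
identically to sensitivity for a binary positive class; report consumers
sometimes expect both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .io_formats import ASD, HC


@dataclass
class EvalReport:
    group: str
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None
    precision: float | None
    recall: float | None
    sensitivity: float | None
    specificity: float | None
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None
    undefined: list[str] = field(default_factory=list)
    labels: list[str] | None = None  # retained for pooled ROC
    scores: list[float] | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {"group": self.group, "n": self.n,
                "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc,
                "undefined": self.undefined}


def _safe_div(num: int, den: int, name: str, undefined: list[str]) -> float | None:
    if den == 0:
        undefined.append(name)
        return None
    return num / den


def _metrics_from_counts(group, tp, fp, tn, fn) -> EvalReport:
    undefined: list[str] = []
    total = tp + fp + tn + fn
    sens = _safe_div(tp, tp + fn, "sensitivity", undefined)
    rep = EvalReport(
        group=group, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_safe_div(tp + tn, total, "accuracy", undefined),
        precision=_safe_div(tp, tp + fp, "precision", undefined),
        recall=sens,  # identical definition for the binary positive class
        sensitivity=sens,
        specificity=_safe_div(tn, tn + fp, "specificity", undefined),
        undefined=undefined)
    return rep


def confusion_metrics(labels, predictions, scores=None,
                      group: str = "overall") -> EvalReport:
    """Confusion counts and derived metrics; ASD is the positive class.

    `labels` and `predictions` are sequences of "ASD"/"HC" strings; when
    real-valued `scores` (probability of ASD) are supplied the ROC curve
    and AUC are attached as well.
    """
    labels = list(labels)
    predictions = list(predictions)
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions differ in length")
    for val in (*labels, *predictions):
        if val not in (ASD, HC):
            raise ValueError(f"labels must be {ASD!r} or {HC!r}, got {val!r}")
    tp = sum(1 for t, p in zip(labels, predictions) if t == ASD and p == ASD)
    fn = sum(1 for t, p in zip(labels, predictions) if t == ASD and p == HC)
    tn = sum(1 for t, p in zip(labels, predictions) if t == HC and p == HC)
    fp = sum(1 for t, p in zip(labels, predictions) if t == HC and p == ASD)
    rep = _metrics_from_counts(group, tp, fp, tn, fn)
    if scores is not None:
        scores = [float(s) for s in scores]
        rep.labels, rep.scores = labels, scores
        rep.roc, rep.auc = roc_curve(labels, scores)
        if rep.auc is None:
            rep.undefined.append("auc")
    return rep


def roc_curve(labels, scores) -> tuple[list[tuple[float, float]], float | None]:
    """ROC points (FPR, TPR) over all score thresholds, plus trapezoidal AUC.

    Thresholds sweep the unique scores with ties grouped. If only one class
    is present the curve and AUC are undefined (None).
    """
    y = np.array([1 if lab == ASD else 0 for lab in labels])
    s = np.asarray(scores, dtype=np.float64)
    if len(y) == 0 or y.min() == y.max():
        return [], None
    fpr, tpr, _ = skm.roc_curve(y, s)
    return list(zip(fpr.tolist(), tpr.tolist())), float(skm.auc(fpr, tpr))


def aggregate(reports: list[EvalReport]) -> pd.DataFrame:
    """Per-group rows plus a pooled row recomputed from summed counts.

    Pooled ROC/AUC is computed from the concatenated scores when every
    report retains them; otherwise the pooled AUC column is left empty.
    """
    if not reports:
        raise ValueError("need at least one report to aggregate")
    rows = [r.to_dict() for r in reports]
    pooled = _metrics_from_counts(
        "pooled",
        sum(r.tp for r in reports), sum(r.fp for r in reports),
        sum(r.tn for r in reports), sum(r.fn for r in reports))
    if all(r.scores is not None for r in reports):
        all_labels = [lab for r in reports for lab in r.labels]
        all_scores = [s for r in reports for s in r.scores]
        pooled.roc, pooled.auc = roc_curve(all_labels, all_scores)
    rows.append(pooled.to_dict())
    return pd.DataFrame(rows)


def format_table(df: pd.DataFrame) -> str:
    """Plain-text metric table (percentages to two decimals)."""
    show = df.copy()
    for col in ("accuracy", "precision", "recall", "sensitivity",
                "specificity", "auc"):
        if col in show:
            show[col] = [f"{100 * v:.2f}" if v is not None and not pd.isna(v)
                         else "-" for v in show[col]]
    cols = [c for c in ("group", "n", "accuracy", "precision", "recall",
                        "sensitivity", "specificity", "auc") if c in show]
    return show[cols].to_string(index=False)
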