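"""Confusion-count metrics and ROC/AUC.

Six metrics are derived from the confusion counts:

    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)        (identical to recall)
    F-score     = 2 * precision * recall / (precision + recall)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)

A metric whose denominator is zero is *undefined* (``None``), not an error;
the F-score is undefined when precision or recall is.  The ROC curve sweeps
the decision cut-off over all distinct scores (ties collapse to one step)
and the AUC is its trapezoidal integral, which equals the Mann-Whitney
pairwise-ranking statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """The six metrics; ``None`` marks an undefined (0/0) value."""

    precision: float | None = None
    recall: float | None = None
    specificity: float | None = None
    sensitivity: float | None = None
    f_score: float | None = None
    accuracy: float | None = None

    def to_dict(self) -> dict[str, float | None]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "f_score": self.f_score,
            "accuracy": self.accuracy,
        }


def confusion(labels, predicted_labels) -> ConfusionCounts:
    """Exact confusion counts for binary labels and predictions."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Derive the six metrics from confusion counts (0/0 -> undefined)."""
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    if precision is None or recall is None or precision + recall == 0:
        f_score = None
    else:
        f_score = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        precision=precision,
        recall=recall,
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        sensitivity=recall,
        f_score=f_score,
        accuracy=_ratio(counts.tp + counts.tn, counts.n),
    )


@dataclass
class RocCurve:
    """ROC points from a cut-off sweep: (FPR, TPR), starting at (0,0),
    ending at (1,1), monotone in both coordinates."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# auc\t{self.auc:.6f}\nfpr\ttpr\n")
            for x, y in zip(self.fpr, self.tpr):
                fh.write(f"{x:.6g}\t{y:.6g}\n")


def roc_auc(labels, scores) -> RocCurve:
    """ROC curve and trapezoidal AUC from real-valued scores.

    The cut-off sweeps over the distinct score values from high to low;
    tied scores contribute a single threshold step.  Requires both classes
    present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {s.shape} scores")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present in labels")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # indices where the score drops: one ROC point per distinct cut-off
    step = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.empty(0, dtype=int)
    last = np.append(step, len(s_sorted) - 1)
    tps = np.cumsum(y_sorted)[last]
    fps = np.cumsum(1 - y_sorted)[last]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[last]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc, thresholds=thresholds)


def write_metrics_table(reports: dict[str, MetricsReport], path: str | Path) -> None:
    """Tab-separated classifier x metric table ('NA' for undefined)."""
    cols = ["precision", "recall", "specificity", "sensitivity", "f_score", "accuracy"]
    with open(path, "w") as fh:
        fh.write("classifier\t" + "\t".join(cols) + "\n")
        for name, rep in reports.items():
            d = rep.to_dict()
            fh.write(
                name
                + "\t"
                + "\t".join("NA" if d[c] is None else f"{d[c]:.4f}" for c in cols)
                + "\n"
            )
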