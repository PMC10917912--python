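"""Multiclass evaluation: confusion matrix, one-vs-rest P/R/F1, ROC/AUC.

For K classes every metric is computed one-vs-rest: class ``c`` supplies
TP (true c predicted c), FP (other classes predicted c), FN (true c
predicted elsewhere) and TN (the rest), from which

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F1 = 2 * precision * recall / (precision + recall)

Overall accuracy is trace / total; macro-F1 (and macro precision/recall)
are unweighted means over classes.  ROC curves sweep a threshold over
the real-valued class scores; AUC is the trapezoidal area and macro AUC
the unweighted mean of the per-class areas.

Cells with a zero denominator (a class never predicted, say) are defined
as 0 and logged, so reports stay total on degenerate inputs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PredictionRecord:
    """Per-image result: class scores, predicted label, true label."""

    scores: np.ndarray
    predicted: int
    true: int
    path: str = ""

    @classmethod
    def from_scores(cls, scores, true: int, path: str = "") -> "PredictionRecord":
        scores = np.asarray(scores, dtype=float)
        return cls(scores=scores, predicted=int(scores.argmax()), true=int(true), path=path)


@dataclass
class ConfusionMatrix:
    """K x K count table: rows are true classes, columns predictions."""

    counts: np.ndarray
    class_labels: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = self.counts.shape[0]
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if not self.class_labels:
            self.class_labels = [f"stage{i + 1}" for i in range(k)]

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> Tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class ``c``."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum() - tp)
        fn = int(self.counts[c, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def normalized(self) -> np.ndarray:
        """Row-normalised (by true-class count) rates; zero rows stay zero."""
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore"):
            out = np.where(row > 0, self.counts / row, 0.0)
        return out


def confusion_matrix(
    records: Sequence[PredictionRecord], num_classes: int, class_labels: Optional[List[str]] = None
) -> ConfusionMatrix:
    if not records:
        raise ValueError("no records to tabulate")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    for r in records:
        if not (0 <= r.true < num_classes) or not (0 <= r.predicted < num_classes):
            raise ValueError(
                f"label out of range [0, {num_classes}): true={r.true} predicted={r.predicted}"
            )
        counts[r.true, r.predicted] += 1
    return ConfusionMatrix(counts, class_labels or [])


@dataclass
class MetricReport:
    """Per-class and macro-averaged classification metrics."""

    class_labels: List[str]
    per_class_precision: List[float]
    per_class_recall: List[float]
    per_class_f1: List[float]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class_auc: Dict[str, float] = field(default_factory=dict)
    macro_auc: Optional[float] = None
    roc_points: Dict[str, List[Tuple[float, float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_labels": self.class_labels,
            "per_class": {
                lab: {
                    "precision": self.per_class_precision[i],
                    "recall": self.per_class_recall[i],
                    "f1": self.per_class_f1[i],
                    **(
                        {"auc": self.per_class_auc[lab]}
                        if lab in self.per_class_auc
                        else {}
                    ),
                }
                for i, lab in enumerate(self.class_labels)
            },
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reporting 0", what)
        return 0.0
    return num / den


def prf_accuracy(cm: ConfusionMatrix) -> MetricReport:
    """Precision/recall/F1 per class plus overall accuracy and macro means."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precs, recs, f1s = [], [], []
    for c in range(cm.num_classes):
        tp, fp, fn, _ = cm.one_vs_rest(c)
        p = _safe_div(tp, tp + fp, f"precision[{cm.class_labels[c]}]")
        r = _safe_div(tp, tp + fn, f"recall[{cm.class_labels[c]}]")
        f = _safe_div(2 * p * r, p + r, f"f1[{cm.class_labels[c]}]")
        precs.append(p)
        recs.append(r)
        f1s.append(f)
    return MetricReport(
        class_labels=list(cm.class_labels),
        per_class_precision=precs,
        per_class_recall=recs,
        per_class_f1=f1s,
        accuracy=np.trace(cm.counts) / cm.total,
        macro_precision=float(np.mean(precs)),
        macro_recall=float(np.mean(recs)),
        macro_f1=float(np.mean(f1s)),
    )


def roc_curve_binary(scores: np.ndarray, positives: np.ndarray) -> List[Tuple[float, float]]:
    """One-vs-rest ROC points (FPR, TPR), thresholds swept over the scores.

    Tied scores collapse onto one point; the curve starts at (0, 0) and
    ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    order = np.argsort(-scores, kind="stable")
    sorted_pos = positives[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep only the last index of each tied-score run
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    keep = np.r_[distinct, sorted_pos.size - 1]
    tpr = tps[keep] / max(n_pos, 1)
    fpr = fps[keep] / max(n_neg, 1)
    pts = [(0.0, 0.0)] + list(zip(fpr.tolist(), tpr.tolist()))
    return pts


def _trapezoid_auc(points: Sequence[Tuple[float, float]]) -> float:
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return float(np.trapezoid(ys, xs))


def roc_auc(records: Sequence[PredictionRecord], num_classes: int,
            class_labels: Optional[List[str]] = None) -> MetricReport:
    """Per-class one-vs-rest ROC/AUC and their macro average.

    Classes absent from the truth have undefined AUC; they are excluded
    from the macro mean with a warning.
    """
    if not records:
        raise ValueError("no records to evaluate")
    labels = class_labels or [f"stage{i + 1}" for i in range(num_classes)]
    truth = np.array([r.true for r in records])
    scores = np.stack([r.scores for r in records])
    if scores.shape[1] != num_classes:
        raise ValueError(f"records carry {scores.shape[1]} scores, expected {num_classes}")
    per_auc: Dict[str, float] = {}
    roc_points: Dict[str, List[Tuple[float, float]]] = {}
    for c in range(num_classes):
        pos = truth == c
        if not pos.any() or pos.all():
            logger.warning("class %s absent from truth or ubiquitous; AUC undefined", labels[c])
            continue
        pts = roc_curve_binary(scores[:, c], pos)
        roc_points[labels[c]] = pts
        per_auc[labels[c]] = _trapezoid_auc(pts)
    macro = float(np.mean(list(per_auc.values()))) if per_auc else None
    return MetricReport(
        class_labels=labels,
        per_class_precision=[],
        per_class_recall=[],
        per_class_f1=[],
        accuracy=float("nan"),
        macro_precision=float("nan"),
        macro_recall=float("nan"),
        macro_f1=float("nan"),
        per_class_auc=per_auc,
        macro_auc=macro,
        roc_points=roc_points,
    )


def full_report(records: Sequence[PredictionRecord], num_classes: int,
                class_labels: Optional[List[str]] = None) -> Tuple[MetricReport, ConfusionMatrix]:
    """Complete report: confusion-matrix metrics merged with ROC/AUC."""
    cm = confusion_matrix(records, num_classes, class_labels)
    report = prf_accuracy(cm)
    auc_part = roc_auc(records, num_classes, class_labels)
    report.per_class_auc = auc_part.per_class_auc
    report.macro_auc = auc_part.macro_auc
    report.roc_points = auc_part.roc_points
    return report, cm


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_confusion_csv(cm: ConfusionMatrix, path, normalized: bool = False) -> None:
    table = cm.normalized() if normalized else cm.counts
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred"] + cm.class_labels)
        for lab, row in zip(cm.class_labels, table):
            writer.writerow([lab] + [f"{v:.6f}" if normalized else int(v) for v in row])


def write_report_json(report: MetricReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def write_roc_csv(report: MetricReport, out_dir) -> List[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for lab, pts in report.roc_points.items():
        p = out_dir / f"roc_{lab}.csv"
        with open(p, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fpr", "tpr"])
            writer.writerows(pts)
        paths.append(p)
    return paths


def plot_roc(report: MetricReport, path) -> None:
    """Optional one-vs-rest ROC plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for lab, pts in report.roc_points.items():
        xs, ys = zip(*pts)
        ax.plot(xs, ys, label=f"{lab} (AUC {report.per_class_auc[lab]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    if report.macro_auc is not None:
        ax.set_title(f"One-vs-rest ROC (macro AUC {report.macro_auc:.3f})")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion(cm: ConfusionMatrix, path, normalized: bool = True) -> None:
    """Optional confusion-matrix heat map (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = cm.normalized() if normalized else cm.counts
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(table, cmap="Blues", vmin=0)
    ax.set_xticks(range(cm.num_classes), cm.class_labels, rotation=45)
    ax.set_yticks(range(cm.num_classes), cm.class_labels)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    for i in range(cm.num_classes):
        for j in range(cm.num_classes):
            v = table[i, j]
            ax.text(j, i, f"{v:.2f}" if normalized else str(int(v)),
                    ha="center", va="center", fontsize=8)
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
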