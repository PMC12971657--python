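"""Classification metrics: confusion counts, precision/recall/F1, rank AUC.

All quantities are computed from first principles.  Multi-class scores are
macro-averaged (unweighted mean over classes); micro averages are reported
alongside but are not the headline.  The one-vs-rest AUC uses the
Mann-Whitney rank identity

    AUC = (sum of positive-sample ranks - M(M+1)/2) / (M * N)

with ascending mid-ranks for ties (M positives, N negatives), which equals
the probability that a random positive outscores a random negative, ties
counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0


def confusion(y_true, y_pred, k: int):
    """Per-class one-vs-rest counts and the K x K confusion matrix
    (rows = true class, columns = predicted class)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= k):
            raise ValueError(f"{name} contains labels outside [0, {k})")
    matrix = np.zeros((k, k), dtype=np.int64)
    np.add.at(matrix, (y_true, y_pred), 1)
    counts = []
    total = int(matrix.sum())
    for c in range(k):
        tp = int(matrix[c, c])
        fn = int(matrix[c].sum() - tp)
        fp = int(matrix[:, c].sum() - tp)
        counts.append(ConfusionCounts(tp=tp, tn=total - tp - fn - fp,
                                      fp=fp, fn=fn))
    return counts, matrix


def prf1(c: ConfusionCounts):
    """Precision, recall and F1 with the zero-denominator-gives-zero
    convention."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    return precision, recall, f1


def auc_rank(scores, is_positive) -> float:
    """One-vs-rest AUC from the rank statistic (mid-ranks for ties)."""
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(is_positive, dtype=bool)
    if scores.shape != pos.shape:
        raise ValueError("scores and labels differ in length")
    m = int(pos.sum())
    n = int((~pos).sum())
    if m == 0:
        raise ValueError("no positive samples; AUC undefined")
    if n == 0:
        raise ValueError("no negative samples; AUC undefined")
    ranks = rankdata(scores, method="average")
    return float((ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n))


def roc_points(scores, is_positive):
    """(FPR, TPR) points of the ROC curve, via scikit-learn."""
    from sklearn.metrics import roc_curve
    fpr, tpr, _ = roc_curve(np.asarray(is_positive, dtype=int),
                            np.asarray(scores, dtype=np.float64))
    return fpr, tpr


@dataclass
class MetricsReport:
    accuracy: float
    per_class_precision: list
    per_class_recall: list
    per_class_f1: list
    per_class_auc: list
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auc: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    confusion_matrix: np.ndarray
    roc_curves: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            **{f"precision_class{c}": v
               for c, v in enumerate(self.per_class_precision)},
            **{f"recall_class{c}": v
               for c, v in enumerate(self.per_class_recall)},
            **{f"f1_class{c}": v for c, v in enumerate(self.per_class_f1)},
            **{f"auc_class{c}": v for c, v in enumerate(self.per_class_auc)},
        }

    def save(self, path):
        """Flat key/value report file."""
        with open(path, "w") as fh:
            for key, val in self.to_dict().items():
                fh.write(f"{key}\t{val:.6f}\n")
            for row in self.confusion_matrix:
                fh.write("confusion\t" + ",".join(map(str, row)) + "\n")

    def save_roc_csv(self, directory):
        """Per-class two-column (FPR, TPR) CSV files."""
        import pathlib
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for c, (fpr, tpr) in self.roc_curves.items():
            with open(directory / f"roc_class{c}.csv", "w") as fh:
                fh.write("fpr,tpr\n")
                for f, t in zip(fpr, tpr):
                    fh.write(f"{f:.8f},{t:.8f}\n")


def evaluate(scores: np.ndarray, y_true) -> MetricsReport:
    """Full report from a per-class probability matrix (rows ~ sum to 1)."""
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError(f"scores shape {scores.shape} incompatible with "
                         f"{y_true.shape[0]} labels")
    k = scores.shape[1]
    y_pred = scores.argmax(axis=1)
    counts, matrix = confusion(y_true, y_pred, k)
    per_p, per_r, per_f = [], [], []
    for c in counts:
        p, r, f = prf1(c)
        per_p.append(p)
        per_r.append(r)
        per_f.append(f)
    per_auc = []
    curves = {}
    for c in range(k):
        pos = y_true == c
        per_auc.append(auc_rank(scores[:, c], pos))
        curves[c] = roc_points(scores[:, c], pos)
    accuracy = float(np.trace(matrix)) / float(matrix.sum())
    # micro: pool one-vs-rest counts over classes
    tp = sum(c.tp for c in counts)
    fp = sum(c.fp for c in counts)
    fn = sum(c.fn for c in counts)
    micro_p = tp / (tp + fp) if tp + fp else 0.0
    micro_r = tp / (tp + fn) if tp + fn else 0.0
    micro_f = (2 * micro_p * micro_r / (micro_p + micro_r)
               if micro_p + micro_r else 0.0)
    return MetricsReport(
        accuracy=accuracy,
        per_class_precision=per_p, per_class_recall=per_r,
        per_class_f1=per_f, per_class_auc=per_auc,
        macro_precision=float(np.mean(per_p)),
        macro_recall=float(np.mean(per_r)),
        macro_f1=float(np.mean(per_f)),
        macro_auc=float(np.mean(per_auc)),
        micro_precision=micro_p, micro_recall=micro_r, micro_f1=micro_f,
        confusion_matrix=matrix, roc_curves=curves)
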