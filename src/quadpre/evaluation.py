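"""Multiclass evaluation: one-vs-rest reductions, rates, MCC and ROC/AUC.

The central object is the 6x6 confusion matrix over the class order
(1, 2, 3, 4, 6, 8): entry (i, j) counts sequences of true class i
predicted as class j.  Each class is reduced one-vs-rest to
TP/FP/FN/TN, from which the standard binary metrics follow:

    ACC = (TP + TN) / N
    TPR = TP / (TP + FN)        FPR = FP / (FP + TN)
    SPC = TN / (FP + TN) = 1 - FPR
    PPV = TP / (TP + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

Undefined ratios (zero denominators) return 0 with an explicit flag
rather than NaN.  The report also carries the unweighted six-class
averages of each metric and the multiclass accuracy trace/N.  AUC is
the rank-based (Mann-Whitney) area with ties counted half, equal to the
trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .core_io import CLASS_NAMES, OLIGOMER_CLASSES

CLASS_ORDER: Tuple[int, ...] = OLIGOMER_CLASSES

_RATE_KEYS = ("acc", "tpr", "fpr", "spc", "ppv", "mcc")


@dataclass(frozen=True)
class BinaryCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def as_confusion_matrix(cm) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.shape != (6, 6):
        raise ValueError("confusion matrix must be 6x6 over classes (1,2,3,4,6,8)")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    return cm.astype(int)


def binarize(cm, cls: int) -> BinaryCounts:
    """One-vs-rest reduction of the 6x6 matrix for the given class."""
    cm = as_confusion_matrix(cm)
    k = CLASS_ORDER.index(cls)
    tp = int(cm[k, k])
    fn = int(cm[k].sum()) - tp
    fp = int(cm[:, k].sum()) - tp
    tn = int(cm.sum()) - tp - fn - fp
    return BinaryCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics_from_counts(b: BinaryCounts) -> Tuple[Dict[str, float], Dict[str, bool]]:
    """Binary metrics and a per-metric flag marking undefined ratios."""
    flags = {k: False for k in _RATE_KEYS}

    def ratio(num: float, den: float, key: str) -> float:
        if den == 0:
            flags[key] = True
            return 0.0
        return num / den

    acc = (b.tp + b.tn) / b.n
    tpr = ratio(b.tp, b.tp + b.fn, "tpr")
    fpr = ratio(b.fp, b.fp + b.tn, "fpr")
    spc = 1.0 - fpr
    ppv = ratio(b.tp, b.tp + b.fp, "ppv")
    mcc_den = math.sqrt(float(b.tp + b.fn) * (b.tp + b.fp)
                        * (b.tn + b.fp) * (b.tn + b.fn))
    if mcc_den == 0:
        flags["mcc"] = True
        mcc = 0.0
    else:
        mcc = (b.tp * b.tn - b.fp * b.fn) / mcc_den
    return ({"acc": acc, "tpr": tpr, "fpr": fpr, "spc": spc,
             "ppv": ppv, "mcc": mcc}, flags)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based AUC (Mann-Whitney with ties counted half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class MetricReport:
    """Per-class and averaged evaluation metrics."""

    per_class: Dict[int, Dict[str, float]]
    flags: Dict[int, Dict[str, bool]]
    averages: Dict[str, float]
    multiclass_acc: float
    auc: Dict[int, float] = field(default_factory=dict)
    mean_auc: Optional[float] = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_class": {CLASS_NAMES[c]: v for c, v in self.per_class.items()},
            "auc": {CLASS_NAMES[c]: v for c, v in self.auc.items()},
            "averages": self.averages,
            "mean_auc": self.mean_auc,
            "multiclass_acc": self.multiclass_acc,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.format_table() + "\n")

    def format_table(self) -> str:
        """Human-readable table: percentages to 1 decimal, MCC/AUC to 3."""
        header = "metric\t" + "\t".join(
            CLASS_NAMES[c] for c in CLASS_ORDER) + "\taverage"
        lines = [header]
        for key in ("acc", "tpr", "spc", "ppv"):
            row = [f"{self.per_class[c][key] * 100:.1f}%" for c in CLASS_ORDER]
            lines.append(f"{key.upper()}\t" + "\t".join(row)
                         + f"\t{self.averages[key] * 100:.1f}%")
        row = [f"{self.per_class[c]['mcc']:.3f}" for c in CLASS_ORDER]
        lines.append("MCC\t" + "\t".join(row) + f"\t{self.averages['mcc']:.3f}")
        if self.auc:
            row = [f"{self.auc.get(c, float('nan')):.3f}" for c in CLASS_ORDER]
            mean = f"{self.mean_auc:.3f}" if self.mean_auc is not None else "-"
            lines.append("AUC\t" + "\t".join(row) + f"\t{mean}")
        lines.append(f"multiclass ACC\t{self.multiclass_acc * 100:.1f}%")
        return "\n".join(lines)


def per_class_report(
    cm,
    score_lists: Optional[Mapping[int, Tuple[Sequence[float], Sequence[bool]]]] = None,
) -> MetricReport:
    """Full report from a confusion matrix and optional per-class scores.

    ``score_lists`` maps a class to (scores, one-vs-rest truth labels)
    for AUC; when absent, AUC is omitted from the report.
    """
    cm = as_confusion_matrix(cm)
    per_class: Dict[int, Dict[str, float]] = {}
    flags: Dict[int, Dict[str, bool]] = {}
    for cls in CLASS_ORDER:
        metrics, f = metrics_from_counts(binarize(cm, cls))
        per_class[cls] = metrics
        flags[cls] = f
    averages = {key: float(np.mean([per_class[c][key] for c in CLASS_ORDER]))
                for key in _RATE_KEYS}
    multiclass_acc = float(np.trace(cm) / cm.sum())
    auc: Dict[int, float] = {}
    mean_auc = None
    if score_lists:
        for cls in CLASS_ORDER:
            if cls in score_lists:
                scores, labels = score_lists[cls]
                auc[cls] = roc_auc(scores, labels)
        if auc:
            mean_auc = float(np.mean([auc[c] for c in sorted(auc)]))
    return MetricReport(per_class=per_class, flags=flags, averages=averages,
                        multiclass_acc=multiclass_acc, auc=auc, mean_auc=mean_auc)


def roc_curve_points(scores: Sequence[float], labels: Sequence[bool]
                     ) -> np.ndarray:
    """(FPR, TPR) points of the empirical ROC curve, threshold descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tps = np.cumsum(labels)
    fps = np.cumsum(~labels)
    n_pos, n_neg = tps[-1], fps[-1]
    # collapse tied thresholds
    distinct = np.r_[np.nonzero(np.diff(scores[order]))[0], labels.size - 1]
    pts = np.column_stack([fps[distinct] / n_neg, tps[distinct] / n_pos])
    return np.vstack([[0.0, 0.0], pts])


def read_confusion_tsv(path: str | Path) -> np.ndarray:
    """Read a whitespace-separated 6x6 confusion matrix (``#`` comments)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([int(x) for x in line.split()])
    return as_confusion_matrix(np.asarray(rows))


def write_confusion_tsv(cm, path: str | Path) -> None:
    cm = as_confusion_matrix(cm)
    with open(path, "w") as fh:
        fh.write("# rows = true class, columns = predicted class; "
                 "class order 1 2 3 4 6 8\n")
        for row in cm:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")
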