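"""Evaluation metrics for heavily imbalanced binary interaction prediction.

Threshold-dependent metrics derive from the confusion counts at a decision
threshold t, with the call rule yhat = 1 iff score >= t. Threshold-free
ranking metrics are AUROC (ties credited one half, i.e. the Mann-Whitney
rank statistic / trapezoidal ROC area) and AUPRC under the average-precision
convention (recall-weighted sum of precision at each positive-triggering
threshold, no linear interpolation between PR points — the standard
unbiased estimator under strong imbalance; the convention is recorded in
every report).

Zero-denominator cases (e.g. precision with no positive calls) return 0 and
set a flag rather than raising, so per-stratum aggregation stays total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .dataset import TypePair


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


def confusion(labels: Sequence[int], calls: Sequence[int]) -> ConfusionCounts:
    """Confusion counts from ground-truth labels and binary calls."""
    y = np.asarray(labels)
    c = np.asarray(calls)
    if y.shape != c.shape:
        raise ValueError("labels and calls must have the same length")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (c == 1))),
        TN=int(np.sum((y == 0) & (c == 0))),
        FP=int(np.sum((y == 0) & (c == 1))),
        FN=int(np.sum((y == 1) & (c == 0))),
    )


def _safe_div(num: float, den: float, flags: List[str], name: str) -> float:
    if den == 0:
        flags.append(f"{name}: zero denominator, reported as 0")
        return 0.0
    return num / den


def basic_metrics(counts: ConfusionCounts) -> Dict[str, float | List[str]]:
    """Accuracy, recall, specificity, precision, F1 and balanced accuracy."""
    flags: List[str] = []
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    accuracy = _safe_div(tp + tn, counts.total, flags, "accuracy")
    recall = _safe_div(tp, tp + fn, flags, "recall")
    specificity = _safe_div(tn, tn + fp, flags, "specificity")
    precision = _safe_div(tp, tp + fp, flags, "precision")
    f1 = _safe_div(2 * precision * recall, precision + recall, flags, "f1")
    return {
        "accuracy": accuracy,
        "recall": recall,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
        "balanced_accuracy": (recall + specificity) / 2.0,
        "flags": flags,
    }


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (by convention) if any margin is empty."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(den)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("ranking metrics require both classes present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve.

    Equals the probability that a uniformly drawn positive outscores a
    uniformly drawn negative, with ties credited 1/2.
    """
    y = np.asarray(labels)
    _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (average-precision convention)."""
    y = np.asarray(labels)
    _check_two_classes(y)
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def baseline_auprc(n_pos: int, n_neg: int) -> float:
    """Chance-level AUPRC: the positive prevalence pi = n_pos / (n_pos + n_neg)."""
    if n_pos < 0 or n_neg < 0 or n_pos + n_neg == 0:
        raise ValueError("need non-negative counts with at least one instance")
    return n_pos / (n_pos + n_neg)


@dataclass
class MetricBlock:
    """All metrics for one evaluation stratum."""

    counts: ConfusionCounts
    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    auroc: Optional[float]
    auprc: Optional[float]
    prevalence: float
    n: int
    flags: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict:
        d = {
            "TP": self.counts.TP, "TN": self.counts.TN,
            "FP": self.counts.FP, "FN": self.counts.FN,
            "accuracy": self.accuracy, "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision, "recall": self.recall,
            "specificity": self.specificity, "f1": self.f1, "mcc": self.mcc,
            "auroc": self.auroc, "auprc": self.auprc,
            "prevalence": self.prevalence, "n": self.n,
        }
        if self.flags:
            d["flags"] = list(self.flags)
        return d


@dataclass
class MetricsReport:
    """Overall metrics plus one block per interaction type pair."""

    overall: MetricBlock
    per_type: Dict[TypePair, MetricBlock]
    threshold: float
    auprc_convention: str = "average_precision"

    def as_dict(self) -> Dict:
        return {
            "threshold": self.threshold,
            "auprc_convention": self.auprc_convention,
            "overall": self.overall.as_dict(),
            "per_type": {str(tp): blk.as_dict() for tp, blk in sorted(self.per_type.items())},
        }


def _block(scores: np.ndarray, labels: np.ndarray, threshold: float) -> MetricBlock:
    calls = (scores >= threshold).astype(int)
    counts = confusion(labels, calls)
    base = basic_metrics(counts)
    flags = list(base.pop("flags"))
    single_class = len(np.unique(labels)) < 2
    if single_class:
        flags.append("auroc/auprc undefined: single class in stratum")
    return MetricBlock(
        counts=counts,
        mcc=mcc(counts),
        auroc=None if single_class else auroc(scores, labels),
        auprc=None if single_class else auprc(scores, labels),
        prevalence=float(np.mean(labels == 1)),
        n=len(labels),
        flags=flags,
        **base,
    )


def stratified_report(
    scores: Sequence[float],
    labels: Sequence[int],
    type_pairs: Sequence[TypePair],
    threshold: float,
) -> MetricsReport:
    """Overall and per-TypePair metric blocks at a fixed decision threshold.

    Per-type blocks are computed on that stratum only; strata containing a
    single class flag AUROC/AUPRC as undefined instead of erroring.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if not (len(s) == len(y) == len(type_pairs)):
        raise ValueError("scores, labels and type_pairs must align")
    per_type: Dict[TypePair, MetricBlock] = {}
    for tp in sorted(set(type_pairs)):
        mask = np.array([t == tp for t in type_pairs])
        per_type[tp] = _block(s[mask], y[mask], threshold)
    return MetricsReport(overall=_block(s, y, threshold), per_type=per_type,
                         threshold=threshold)
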