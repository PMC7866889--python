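"""Binary-classifier evaluation: Sn, Sp, Acc, MCC and ROC-AUC.

All confusion-matrix metrics are pure functions of (TP, TN, FP, FN):

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

AUC is threshold-free: the Mann-Whitney rank statistic, i.e. the probability
that a uniformly chosen positive outscores a uniformly chosen negative with
ties counted 1/2, which equals the trapezoidal area under the ROC curve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    TSV_HEADER = "method\tdataset\tSn\tSp\tAcc\tMCC\tAUC"

    def tsv_row(self, method: str, dataset: str) -> str:
        return (
            f"{method}\t{dataset}\t{self.sn:.4f}\t{self.sp:.4f}\t{self.acc:.4f}"
            f"\t{self.mcc:.4f}\t{self.auc:.4f}"
        )


def _check_pair(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(f"labels shape {labels.shape} != scores shape {scores.shape}")
    if labels.size == 0:
        raise ValueError("labels/scores must be nonempty")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(np.int64), scores


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN at a threshold; score >= threshold predicts positive."""
    labels, scores = _check_pair(labels, scores)
    predicted = scores >= threshold
    actual = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(predicted & actual)),
        tn=int(np.sum(~predicted & ~actual)),
        fp=int(np.sum(predicted & ~actual)),
        fn=int(np.sum(~predicted & actual)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0.0 when there are no positives."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); 0.0 when there are no negatives."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else 0.0


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("accuracy undefined for empty counts")
    return (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0.0 when any marginal is empty.

    Equals the Pearson correlation between the predicted and true binary
    vectors, hence always lies in [-1, 1].
    """
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def roc_auc(labels, scores) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    Requires both classes present.
    """
    labels, scores = _check_pair(labels, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires at least one sample of each class")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 wins
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: thresholded Sn/Sp/Acc/MCC plus threshold-free AUC."""
    counts = confusion(labels, scores, threshold)
    return MetricsReport(
        sn=sensitivity(counts),
        sp=specificity(counts),
        acc=accuracy(counts),
        mcc=mcc(counts),
        auc=roc_auc(labels, scores),
        counts=counts,
    )
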