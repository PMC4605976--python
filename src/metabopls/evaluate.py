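"""Test-set figures of merit and selection-overlap statistics.

AUC is the Mann-Whitney probability that a positive-class score outranks a
negative-class one (ties count 1/2).  Sensitivity is the percentage of
positive-class (OSAS, by the workflow's convention) test samples predicted
correctly, specificity the percentage of negative-class (COPD) samples
predicted correctly, and efficiency — the non-error rate — the percentage
of all test samples classified correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalReport", "OverlapStat", "auc", "confusion_metrics", "overlap_stats"]


def _tied_ranks(x: np.ndarray) -> np.ndarray:
    """1-based ranks with ties replaced by their average rank."""
    _, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    end = np.cumsum(counts)
    avg = end - (counts - 1) / 2.0
    return avg[inv]


def auc(scores, labels) -> float:
    """Area under the ROC curve of continuous scores against +1/-1 labels.

    Mann-Whitney formulation: the fraction of (positive, negative) sample
    pairs in which the positive score is higher, ties counting 1/2, computed
    from average ranks.  This loop-free rank form is used because the
    bootstrap engine evaluates it thousands of times per run.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos = labels > 0
    n_pos = int(pos.sum())
    n_neg = scores.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = _tied_ranks(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvalReport:
    """Confusion counts and percentage figures of merit for one test set."""

    positive_class: str
    negative_class: str
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    efficiency: float = field(init=False)
    auc_test: float | None = None
    complexity: int | None = None
    variables: list[str] | None = None

    def __post_init__(self) -> None:
        n_pos = self.tp + self.fn
        n_neg = self.tn + self.fp
        if n_pos == 0 or n_neg == 0:
            raise ValueError("both classes must be present in the truth labels")
        self.sensitivity = 100.0 * self.tp / n_pos
        self.specificity = 100.0 * self.tn / n_neg
        self.efficiency = 100.0 * (self.tp + self.tn) / (n_pos + n_neg)

    def as_dict(self) -> dict:
        d = {
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": round(self.sensitivity, 2),
            "specificity": round(self.specificity, 2),
            "efficiency": round(self.efficiency, 2),
        }
        if self.auc_test is not None:
            d["auc_test"] = round(self.auc_test, 4)
        if self.complexity is not None:
            d["complexity"] = self.complexity
        if self.variables is not None:
            d["variables"] = list(self.variables)
        return d


def confusion_metrics(predicted, truth, positive_class: str) -> EvalReport:
    """Sensitivity/specificity/efficiency from hard class assignments."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and true label vectors must align")
    classes = sorted(set(truth))
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} absent from truth")
    if len(classes) != 2:
        raise ValueError("exactly two classes expected in the truth labels")
    negative_class = next(c for c in classes if c != positive_class)
    is_pos = truth == positive_class
    pred_pos = predicted == positive_class
    return EvalReport(
        positive_class=positive_class,
        negative_class=negative_class,
        tp=int(np.sum(is_pos & pred_pos)),
        fn=int(np.sum(is_pos & ~pred_pos)),
        tn=int(np.sum(~is_pos & ~pred_pos)),
        fp=int(np.sum(~is_pos & pred_pos)),
    )


@dataclass
class OverlapStat:
    """Intersection of two selected-variable sets within a block combination."""

    common: list[str]
    count: int
    percent: int  # round(100 * count / block_total)

    def as_dict(self) -> dict:
        return {"common": self.common, "count": self.count, "percent": self.percent}


def overlap_stats(selection_a, selection_b, block_total: int) -> OverlapStat:
    """Common variables between two selections, as a count and a percentage
    of all variables in the block(s) considered (rounded to an integer)."""
    if block_total < 1:
        raise ValueError("block_total must be positive")
    common = sorted(set(selection_a) & set(selection_b))
    return OverlapStat(
        common=common,
        count=len(common),
        percent=round(100.0 * len(common) / block_total),
    )
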