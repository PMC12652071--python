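"""Evaluation metrics for binary variant classification.

All metrics are reported as percents in [0, 100], matching how results
tables in this field are printed: accuracy, AUROC, F1 for the positive
(pathogenic) class, and %TP = TP / (TP + FN) · 100 (recall as a percent).
Confusion counts are always retained alongside the derived metrics
because the TP/TN asymmetry is itself of scientific interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import AurocUndefinedError, InvalidArgumentError, InvalidDataError

#: canonical metric order used across profiles, rules and reports
METRIC_NAMES = ("accuracy", "auroc", "f1", "pct_tp")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise InvalidArgumentError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalResult:
    """One fine-tune + evaluate outcome: counts, percent metrics, timing."""

    counts: ConfusionCounts
    accuracy: float
    auroc: float
    f1: float
    pct_tp: float
    fine_tune_seconds: float = 0.0
    eval_seconds: float = 0.0
    seed: int = 0

    def metric(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise InvalidArgumentError(f"unknown metric {name!r}; use {METRIC_NAMES}")
        return getattr(self, name)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EvalResult":
        d = dict(d)
        d["counts"] = ConfusionCounts(**d["counts"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def metrics_from_counts(counts: ConfusionCounts) -> dict:
    """Accuracy, F1 and %TP (percent scale) derived from confusion counts.

    F1 is the harmonic mean of precision and recall for the positive
    class, defined as 0 when precision + recall is 0.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    total = counts.total
    if total == 0:
        raise InvalidDataError("cannot compute metrics over zero records")
    accuracy = (tp + tn) / total * 100.0
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) * 100.0
        if precision + recall > 0
        else 0.0
    )
    pct_tp = recall * 100.0 if tp + fn > 0 else 0.0
    return {"accuracy": accuracy, "f1": f1, "pct_tp": pct_tp}


def compute_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> EvalResult:
    """Confusion counts and percent metrics at ``score >= threshold ⇒ 1``.

    AUROC uses the rank-based (midrank tie) convention. With only one
    class present AUROC is undefined: :class:`AurocUndefinedError` is
    raised with the partially filled result attached as ``.partial``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1 or labels.size == 0:
        raise InvalidArgumentError("labels and scores must be equal-length 1-D, n >= 1")
    if not np.isin(labels, (0, 1)).all():
        raise InvalidArgumentError("labels must be 0/1")
    if not 0.0 < threshold < 1.0:
        raise InvalidArgumentError("threshold must lie strictly in (0, 1)")
    preds = (scores >= threshold).astype(np.int64)
    counts = ConfusionCounts(
        TP=int(np.sum((preds == 1) & (labels == 1))),
        FP=int(np.sum((preds == 1) & (labels == 0))),
        TN=int(np.sum((preds == 0) & (labels == 0))),
        FN=int(np.sum((preds == 0) & (labels == 1))),
    )
    derived = metrics_from_counts(counts)
    if labels.min() == labels.max():
        partial = EvalResult(counts=counts, auroc=float("nan"), **derived)
        raise AurocUndefinedError(
            "AUROC undefined: only one class present in labels", partial=partial
        )
    auroc = float(roc_auc_score(labels, scores)) * 100.0
    return EvalResult(counts=counts, auroc=auroc, **derived)


def auroc_pair_counting(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Exhaustive pair-counting AUROC (percent): the probability a random
    positive outscores a random negative, ties counted one half.

    O(n_pos · n_neg) — an independent cross-check for small inputs, not
    the production implementation.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidDataError("pair counting needs both classes")
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg)) * 100.0
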