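"""Majority voting across blocks and block-/image-level performance metrics.

An image's label is the plurality class among its block predictions; vote
ties are resolved conservatively in the priority order fat-injected >
regular > Wagyu, so a surface that might be artificially marbled is flagged
rather than excused.

Performance is summarized at both levels by:

* misjudgment rate alpha — truly non-fat-injected items classified as
  fat-injected, over all truly non-fat-injected items (Type I error);
* detection rate / recall (1 - beta) — truly fat-injected items correctly
  detected, over all truly fat-injected items;
* precision — correct fat-injected detections over all fat-injected calls;
* CR — overall three-class accuracy (trace of the confusion matrix over
  its total);
* F1 — harmonic mean of recall and precision for the fat-injected
  one-vs-rest task.

Metrics with a zero denominator (e.g. precision when nothing was detected)
are reported as NaN with a warning, never silently as 0 or 100.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .svm_classifier import CLASS_PRIORITY, BeefClass


@dataclass(frozen=True)
class VoteResult:
    counts: dict[BeefClass, int]
    final: BeefClass
    tie: bool


@dataclass(frozen=True)
class MetricsReport:
    level: str  # "BLOCK" or "IMAGE"
    alpha: float
    recall: float
    precision: float
    cr: float
    f1: float
    n_items: int
    confusion: np.ndarray = field(repr=False)

    def as_dict(self, ndigits: int = 2) -> dict:
        def fmt(v):
            return None if math.isnan(v) else round(v, ndigits)

        return {
            "level": self.level,
            "alpha_pct": fmt(self.alpha),
            "recall_pct": fmt(self.recall),
            "precision_pct": fmt(self.precision),
            "cr_pct": fmt(self.cr),
            "f1_pct": fmt(self.f1),
            "n_items": self.n_items,
        }

    def to_json(self, ndigits: int = 2) -> str:
        return json.dumps(self.as_dict(ndigits), indent=2)

    def __str__(self) -> str:
        d = self.as_dict()
        return (
            f"{self.level:5s}  alpha={d['alpha_pct']}%  recall={d['recall_pct']}%  "
            f"precision={d['precision_pct']}%  CR={d['cr_pct']}%  F1={d['f1_pct']}%  "
            f"(n={self.n_items})"
        )


def vote_image(block_labels) -> VoteResult:
    """Plurality vote over block labels with the conservative tie-break."""
    labels = [BeefClass(int(v)) for v in block_labels]
    if not labels:
        raise ValueError("cannot vote on an empty block-label list")
    counts = Counter(labels)
    best = max(counts.values())
    tied = [c for c, n in counts.items() if n == best]
    final = next(c for c in CLASS_PRIORITY if c in tied)
    return VoteResult(
        counts={c: counts.get(c, 0) for c in BeefClass},
        final=final,
        tie=len(tied) > 1,
    )


def confusion_matrix(predicted, truth) -> np.ndarray:
    """3x3 matrix indexed [true - 1, predicted - 1] over the Wagyu/regular/injected labels."""
    predicted = np.asarray([int(v) for v in predicted])
    truth = np.asarray([int(v) for v in truth])
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError(
            f"predicted and truth must be equal-length nonempty lists, "
            f"got {predicted.shape} and {truth.shape}"
        )
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(truth, predicted):
        cm[t - 1, p - 1] += 1
    return cm


def _safe_rate(numerator: float, denominator: float, name: str) -> float:
    if denominator == 0:
        warnings.warn(f"{name} undefined: zero denominator", RuntimeWarning, stacklevel=3)
        return float("nan")
    return 100.0 * numerator / denominator


def _metrics(predicted, truth, level: str) -> MetricsReport:
    cm = confusion_matrix(predicted, truth)
    inj = BeefClass.FAT_INJECTED - 1
    non_inj_total = cm.sum() - cm[inj].sum()
    false_alarms = cm[:, inj].sum() - cm[inj, inj]
    detected = cm[:, inj].sum()

    alpha = _safe_rate(false_alarms, non_inj_total, "misjudgment rate")
    recall = _safe_rate(cm[inj, inj], cm[inj].sum(), "detection rate")
    precision = _safe_rate(cm[inj, inj], detected, "precision")
    cr = _safe_rate(np.trace(cm), cm.sum(), "classification rate")
    if math.isnan(recall) or math.isnan(precision) or recall + precision == 0:
        if not (math.isnan(recall) or math.isnan(precision)):
            warnings.warn("F1 undefined: recall + precision is zero", RuntimeWarning, stacklevel=3)
        f1 = float("nan")
    else:
        f1 = 2.0 * recall * precision / (recall + precision)
    return MetricsReport(
        level=level,
        alpha=alpha,
        recall=recall,
        precision=precision,
        cr=cr,
        f1=f1,
        n_items=int(cm.sum()),
        confusion=cm,
    )


def block_metrics(predicted, truth) -> MetricsReport:
    """Metrics over individual grid-block predictions."""
    return _metrics(predicted, truth, "BLOCK")


def image_metrics(predicted, truth) -> MetricsReport:
    """Metrics over final per-image labels (after majority voting)."""
    return _metrics(predicted, truth, "IMAGE")
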