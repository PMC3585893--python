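"""Performance evaluation: confusion metrics, leave-one-out CV, penalty grid
search, and nested cross-validation.

Class balance in phenotype panels is typically poor (far more sequenced
non-degraders than degraders), so plain accuracy is misleading.  Performance
is therefore summarised by the macro-accuracy

    MACC = (recall + true negative rate) / 2,

the mean of recall on the positive class (TP / (TP + FN)) and the true
negative rate (TN / (TN + FP)).

The penalty C is tuned over a log-spaced grid C = 10^x.  Unbiased accuracy
comes from nested cross-validation: an outer leave-one-out loop holds out one
sample; an inner leave-one-out grid search over the remaining samples picks
C; a model at that C, trained on all remaining samples, predicts the held-out
one.  Feature scaling is refit inside every fold on training rows only, so no
information about a held-out sample leaks into the model that predicts it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import svm
from .features import FeatureMatrix, scale_apply, scale_training


@dataclass(frozen=True)
class ConfusionCounts:
    """Outcome counts of binary phenotype calls.

    TP: correctly predicted degraders; TN: correctly predicted non-degraders;
    FP: non-degraders called degraders; FN: degraders called non-degraders.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        """Plain fraction of correct calls, (TP + TN) / total."""
        if self.total == 0:
            raise ValueError("no evaluated samples")
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class MetricSet:
    """Recall, true negative rate and their mean (macro-accuracy)."""

    recall: float
    true_negative_rate: float
    macro_accuracy: float

    def rounded(self, ndigits: int = 2) -> "MetricSet":
        """Display convention: metrics are reported to 2 decimals."""
        return MetricSet(
            recall=round(self.recall, ndigits),
            true_negative_rate=round(self.true_negative_rate, ndigits),
            macro_accuracy=round(self.macro_accuracy, ndigits),
        )


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """Compute recall, TNR and MACC from confusion counts.

    Both classes must be represented among the evaluated samples.
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive samples evaluated (TP + FN = 0); recall undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative samples evaluated (TN + FP = 0); TNR undefined")
    recall = counts.tp / (counts.tp + counts.fn)
    tnr = counts.tn / (counts.tn + counts.fp)
    return MetricSet(recall=recall, true_negative_rate=tnr,
                     macro_accuracy=(recall + tnr) / 2)


@dataclass(frozen=True)
class CGrid:
    """Log-spaced candidate values for the penalty, C = 10^x.

    The default spans x = -3.0 to 0.0 in steps of 0.25 (13 values); values of
    C above 1 are excluded by default because model accuracy saturates there.
    """

    exponents: tuple = tuple(np.round(np.arange(-3.0, 0.0 + 1e-9, 0.25), 6))

    def __post_init__(self) -> None:
        exps = tuple(float(x) for x in self.exponents)
        if len(exps) == 0:
            raise ValueError("grid must contain at least one exponent")
        if any(b <= a for a, b in zip(exps, exps[1:])):
            raise ValueError("grid exponents must be strictly increasing")
        object.__setattr__(self, "exponents", exps)

    @property
    def values(self) -> tuple:
        return tuple(10.0 ** x for x in self.exponents)

    @classmethod
    def default(cls) -> "CGrid":
        return cls()

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "CGrid":
        if any(v <= 0 for v in values):
            raise ValueError("C values must be positive")
        return cls(exponents=tuple(sorted(np.log10(v) for v in values)))


@dataclass(frozen=True)
class FoldPrediction:
    sample_id: str
    true_label: int
    predicted_label: int
    decision_value: float
    C: Optional[float] = None  # inner-loop choice, for nested CV


@dataclass(frozen=True)
class CVResult:
    confusion: ConfusionCounts
    metrics: MetricSet
    predictions: tuple


@dataclass(frozen=True)
class GridPoint:
    C: float
    metrics: MetricSet


def _require_labels(dataset: FeatureMatrix, min_per_class: int, context: str) -> None:
    if dataset.labels is None:
        raise ValueError(f"{context} requires a labelled dataset")
    n_pos = int((dataset.labels == 1).sum())
    n_neg = int((dataset.labels == -1).sum())
    if min(n_pos, n_neg) < min_per_class:
        raise ValueError(
            f"{context} requires at least {min_per_class} samples per class "
            f"(found {n_pos} positive, {n_neg} negative)"
        )


def _confusion_from(predictions: Sequence[FoldPrediction]) -> ConfusionCounts:
    tp = sum(1 for p in predictions if p.true_label == 1 and p.predicted_label == 1)
    fn = sum(1 for p in predictions if p.true_label == 1 and p.predicted_label == -1)
    tn = sum(1 for p in predictions if p.true_label == -1 and p.predicted_label == -1)
    fp = sum(1 for p in predictions if p.true_label == -1 and p.predicted_label == 1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _fit_fold(train: FeatureMatrix, C: float, tolerance: float):
    scaled, scaler = scale_training(train)
    model = svm.train(
        scaled.X, scaled.labels, C, tolerance,
        family_ids=scaled.family_ids, encoding=scaled.encoding,
    )
    return model, scaler


def _predict_row(model, scaler, dataset: FeatureMatrix, index: int) -> Tuple[int, float]:
    row = scale_apply(scaler, dataset.take([index]))
    return svm.predict(model, row.X[0])


def loo_cv(dataset: FeatureMatrix, C: float, tolerance: float = 1e-6) -> CVResult:
    """Leave-one-out cross-validation at a fixed penalty C.

    For each sample, the scaler and model are fit on the other l - 1 samples
    and the held-out sample's prediction is recorded.  Deterministic.
    """
    _require_labels(dataset, 2, "leave-one-out CV")
    n = dataset.n_samples
    predictions = []
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        model, scaler = _fit_fold(dataset.take(rest), C, tolerance)
        label, value = _predict_row(model, scaler, dataset, i)
        predictions.append(
            FoldPrediction(
                sample_id=dataset.sample_ids[i],
                true_label=int(dataset.labels[i]),
                predicted_label=label,
                decision_value=value,
                C=C,
            )
        )
    confusion = _confusion_from(predictions)
    return CVResult(confusion=confusion, metrics=confusion_metrics(confusion),
                    predictions=tuple(predictions))


def grid_search(
    dataset: FeatureMatrix, grid: CGrid = CGrid.default(), tolerance: float = 1e-6
) -> List[GridPoint]:
    """Rank penalty values by leave-one-out macro-accuracy.

    One LOO run per C; ranking is by MACC descending with ties broken toward
    the smaller (more regularised, sparser) C.
    """
    points = [GridPoint(C=C, metrics=loo_cv(dataset, C, tolerance).metrics)
              for C in grid.values]
    points.sort(key=lambda p: (-p.metrics.macro_accuracy, p.C))
    return points


def nested_cv(
    dataset: FeatureMatrix, grid: CGrid = CGrid.default(), tolerance: float = 1e-6
) -> CVResult:
    """Nested cross-validation: unbiased accuracy with per-fold C selection.

    Outer loop is leave-one-out.  In each outer fold an inner leave-one-out
    grid search over the l - 1 remaining samples picks the best C; a model at
    that C trained on all l - 1 samples predicts the held-out sample.  The
    confusion is aggregated over all outer folds.
    """
    _require_labels(dataset, 3, "nested CV")
    n = dataset.n_samples
    predictions = []
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        inner = dataset.take(rest)
        best_c = grid_search(inner, grid, tolerance)[0].C
        model, scaler = _fit_fold(inner, best_c, tolerance)
        label, value = _predict_row(model, scaler, dataset, i)
        predictions.append(
            FoldPrediction(
                sample_id=dataset.sample_ids[i],
                true_label=int(dataset.labels[i]),
                predicted_label=label,
                decision_value=value,
                C=best_c,
            )
        )
    confusion = _confusion_from(predictions)
    return CVResult(confusion=confusion, metrics=confusion_metrics(confusion),
                    predictions=tuple(predictions))


def cv_report(result: CVResult) -> dict:
    """JSON-serialisable summary of a CV run (raw and 2-dp display metrics)."""
    shown = result.metrics.rounded()
    return {
        "confusion": {
            "tp": result.confusion.tp,
            "fp": result.confusion.fp,
            "tn": result.confusion.tn,
            "fn": result.confusion.fn,
        },
        "metrics": {
            "recall": result.metrics.recall,
            "true_negative_rate": result.metrics.true_negative_rate,
            "macro_accuracy": result.metrics.macro_accuracy,
        },
        "metrics_2dp": {
            "recall": shown.recall,
            "true_negative_rate": shown.true_negative_rate,
            "macro_accuracy": shown.macro_accuracy,
        },
        "predictions": [
            {
                "sample_id": p.sample_id,
                "true_label": p.true_label,
                "predicted_label": p.predicted_label,
                "decision_value": p.decision_value,
                "C": p.C,
            }
            for p in result.predictions
        ],
    }
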