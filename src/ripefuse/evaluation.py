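"""Classification metrics: confusion matrices, one-vs-rest tallies, and the
accuracy / precision / recall formulas.

The binary definitions are

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision =  TP / (TP + FP)
    recall    =  TP / (TP + FN)

For the 3-class task they are applied one-vs-rest per class and macro-averaged
(unweighted mean); per-class values are reported alongside so either reading
is available.  Zero denominators return 0 with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "BinaryTally",
    "confusion_matrix",
    "binary_tally",
    "accuracy",
    "precision",
    "recall",
    "metrics_from_confusion",
    "MetricsReport",
    "evaluate_classifier",
]


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = number of samples with true class i predicted as class j."""

    classes: List[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion_matrix(
    truth: Sequence, predictions: Sequence, classes: Sequence[str]
) -> ConfusionMatrix:
    truth = [str(t) for t in truth]
    predictions = [str(p) for p in predictions]
    if len(truth) != len(predictions):
        raise ValueError("truth and predictions must have equal length")
    classes = [str(c) for c in classes]
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predictions):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass(frozen=True)
class BinaryTally:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def binary_tally(cm: ConfusionMatrix, positive_class: str) -> BinaryTally:
    """One-vs-rest reduction of a multiclass confusion matrix."""
    if positive_class not in cm.classes:
        raise ValueError(f"{positive_class!r} is not one of {cm.classes}")
    p = cm.classes.index(positive_class)
    tp = int(cm.counts[p, p])
    fp = int(cm.counts[:, p].sum()) - tp
    fn = int(cm.counts[p, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return BinaryTally(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning 0")
        return 0.0
    return num / den


def accuracy(t: BinaryTally) -> float:
    return _ratio(t.tp + t.tn, t.total, "accuracy")


def precision(t: BinaryTally) -> float:
    return _ratio(t.tp, t.tp + t.fp, "precision")


def recall(t: BinaryTally) -> float:
    return _ratio(t.tp, t.tp + t.fn, "recall")


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    """Overall accuracy plus per-class and macro one-vs-rest metrics."""
    per_class = {}
    for c in cm.classes:
        t = binary_tally(cm, c)
        per_class[c] = {
            "accuracy": accuracy(t),
            "precision": precision(t),
            "recall": recall(t),
        }
    macro = {
        m: float(np.mean([per_class[c][m] for c in cm.classes]))
        for m in ("precision", "recall")
    }
    return {
        "accuracy": cm.overall_accuracy,
        "per_class": per_class,
        "macro_precision": macro["precision"],
        "macro_recall": macro["recall"],
    }


@dataclass
class MetricsReport:
    """Per-split confusion matrices and metrics, plus the training loss history."""

    classes: List[str]
    splits: Dict[str, dict] = field(default_factory=dict)  # split -> metrics dict
    confusions: Dict[str, ConfusionMatrix] = field(default_factory=dict)
    loss_history: Optional[dict] = None

    def add_split(self, name: str, cm: ConfusionMatrix) -> None:
        self.confusions[name] = cm
        self.splits[name] = metrics_from_confusion(cm)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "splits": self.splits,
            "confusions": {k: cm.counts.tolist() for k, cm in self.confusions.items()},
            "loss_history": self.loss_history,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text_table(self) -> str:
        """Accuracy / macro precision / macro recall by split, as a text table."""
        names = [n for n in ("train", "val", "test") if n in self.splits] + [
            n for n in self.splits if n not in ("train", "val", "test")
        ]
        rows = []
        for metric, key in (
            ("Accuracy", "accuracy"),
            ("Precision", "macro_precision"),
            ("Recall", "macro_recall"),
        ):
            rows.append(
                {"Metric": metric, **{n: f"{self.splits[n][key] * 100:.1f}%" for n in names}}
            )
        return pd.DataFrame(rows).to_string(index=False)


def evaluate_classifier(
    model,
    x: np.ndarray,
    y: np.ndarray,
    split_indices: Dict[str, np.ndarray],
    classes: Optional[Sequence[str]] = None,
    batch_size: int = 64,
) -> MetricsReport:
    """Run a trained model over each split and build a metrics report.

    ``y`` holds integer class indices into ``classes`` (default "0","1",...).
    Empty splits are rejected.
    """
    from .nn import predict_logits

    n_classes = int(y.max()) + 1 if len(y) else 0
    classes = [str(c) for c in (classes if classes is not None else range(n_classes))]
    report = MetricsReport(classes=list(classes))
    for name, idx in split_indices.items():
        idx = np.asarray(idx, dtype=int)
        if len(idx) == 0:
            raise ValueError(f"split {name!r} is empty")
        pred = predict_logits(model, x[idx], batch_size=batch_size).argmax(axis=1)
        cm = confusion_matrix(
            [classes[i] for i in y[idx]], [classes[i] for i in pred], classes
        )
        report.add_split(name, cm)
    return report
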