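"""Tile-level evaluation: balanced accuracy, macro metrics, binary collapse.

Balanced accuracy for the multiclass problem is the macro-average of
per-class recall; precision, recall and F1 are macro-averaged one-vs-all
(equal class weights), with macro-F1 the mean of per-class F1 values (not
the F1 of macro-precision/recall).  A never-predicted class contributes
precision 0 with a warning rather than an exception.  The five-class matrix
can also be collapsed to binary tumor detection ("tumor" = the glioma
subtypes, "no tumor" = normal tissue/necrosis), yielding a false-alarm rate
and a missed-cancer rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .scheme import DEFAULT_SCHEME, ClassScheme

__all__ = [
    "ConfusionMatrix",
    "MacroMetrics",
    "MetricsReport",
    "confusion_matrix",
    "balanced_accuracy",
    "macro_metrics",
    "per_class_metrics",
    "binary_collapse",
    "metrics_report",
]


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} labels"
            )
        if np.any(self.counts < 0):
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def support(self) -> np.ndarray:
        """Per-class true counts (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    scheme: ClassScheme | Sequence[str] = DEFAULT_SCHEME,
) -> ConfusionMatrix:
    """Tally true/predicted label pairs into a fixed-order matrix."""
    labels = tuple(scheme.labels) if isinstance(scheme, ClassScheme) else tuple(scheme)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    known = set(labels)
    for seq, name in ((true_labels, "true"), (predicted_labels, "predicted")):
        unknown = {lab for lab in seq if lab not in known}
        if unknown:
            raise ValueError(f"unknown {name} labels: {sorted(unknown)}")
    if len(true_labels) == 0:
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    else:
        counts = _sk_confusion_matrix(
            list(true_labels), list(predicted_labels), labels=list(labels)
        )
    return ConfusionMatrix(counts=counts, labels=labels)


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean per-class recall over classes with non-zero support.

    Zero-support classes are excluded with a warning; an all-zero matrix is
    an error.
    """
    support = cm.support
    if cm.total == 0:
        raise ValueError("cannot compute balanced accuracy of an empty matrix")
    zero = [lab for lab, s in zip(cm.labels, support) if s == 0]
    if zero:
        warnings.warn(
            f"classes with zero support excluded from balanced accuracy: {zero}",
            UserWarning,
            stacklevel=2,
        )
    mask = support > 0
    recalls = np.diag(cm.counts)[mask] / support[mask]
    return float(recalls.mean())


class MacroMetrics(NamedTuple):
    precision: float
    recall: float
    f1: float


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """One-vs-all precision/recall/F1/support per class.

    Precision of a never-predicted class is 0 (with a warning); recall of a
    zero-support class is 0; F1 is 0 whenever precision + recall is 0.
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics of an empty matrix")
    diag = np.diag(cm.counts).astype(np.float64)
    support = cm.support.astype(np.float64)
    predicted = cm.counts.sum(axis=0).astype(np.float64)
    never = [lab for lab, p in zip(cm.labels, predicted) if p == 0]
    if never:
        warnings.warn(
            f"never-predicted classes get precision 0: {never}",
            UserWarning,
            stacklevel=2,
        )
    out = {}
    for i, lab in enumerate(cm.labels):
        prec = diag[i] / predicted[i] if predicted[i] > 0 else 0.0
        rec = diag[i] / support[i] if support[i] > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        out[lab] = {
            "precision": float(prec),
            "recall": float(rec),
            "f1": float(f1),
            "support": int(support[i]),
        }
    return out


def macro_metrics(cm: ConfusionMatrix) -> MacroMetrics:
    """Equal-weight averages of the one-vs-all per-class metrics.

    Macro recall averages over classes with support only (so it equals
    balanced accuracy); macro precision and F1 average over all classes,
    with never-predicted classes contributing 0.
    """
    per = per_class_metrics(cm)
    support_mask = cm.support > 0
    recalls = [m["recall"] for m, s in zip(per.values(), support_mask) if s]
    precisions = [m["precision"] for m in per.values()]
    f1s = [m["f1"] for m in per.values()]
    return MacroMetrics(
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
    )


def binary_collapse(
    cm: ConfusionMatrix, scheme: ClassScheme = DEFAULT_SCHEME
) -> tuple[float, float]:
    """Collapse to tumor / no-tumor and return (false_alarm, missed_cancer).

    ``false_alarm`` is P(predicted tumor | true non-tumor); ``missed_cancer``
    is P(predicted non-tumor | true tumor).  Tumor-subtype confusions stay
    within the tumor partition and leave both rates untouched.
    """
    tumor_idx = [i for i, lab in enumerate(cm.labels) if lab in scheme.tumor_labels]
    non_idx = [i for i, lab in enumerate(cm.labels) if lab not in scheme.tumor_labels]
    if not tumor_idx or not non_idx:
        raise ValueError("both sides of the tumor partition must be non-empty")
    c = cm.counts
    n_tumor = c[np.ix_(tumor_idx, range(len(cm.labels)))].sum()
    n_non = c[np.ix_(non_idx, range(len(cm.labels)))].sum()
    if n_tumor == 0 or n_non == 0:
        raise ValueError(
            "binary collapse needs support on both sides of the partition"
        )
    false_alarm = c[np.ix_(non_idx, tumor_idx)].sum() / n_non
    missed = c[np.ix_(tumor_idx, non_idx)].sum() / n_tumor
    return float(false_alarm), float(missed)


@dataclass
class MetricsReport:
    """Per-class, macro and binary-collapse metrics of one confusion matrix."""

    confusion: ConfusionMatrix
    per_class: dict[str, dict[str, float]]
    balanced_accuracy: float
    macro: MacroMetrics
    false_alarm_rate: float | None = None
    missed_cancer_rate: float | None = None

    def to_dict(self) -> dict:
        return {
            "labels": list(self.confusion.labels),
            "confusion": self.confusion.counts.tolist(),
            "per_class": self.per_class,
            "macro": {
                "balanced_accuracy": self.balanced_accuracy,
                "precision": self.macro.precision,
                "recall": self.macro.recall,
                "f1": self.macro.f1,
            },
            "binary": {
                "false_alarm_rate": self.false_alarm_rate,
                "missed_cancer_rate": self.missed_cancer_rate,
            },
        }


def metrics_report(
    cm: ConfusionMatrix, scheme: ClassScheme = DEFAULT_SCHEME
) -> MetricsReport:
    """Full report; the binary collapse is omitted when a side lacks support."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ba = balanced_accuracy(cm)
        per = per_class_metrics(cm)
        macro = macro_metrics(cm)
    try:
        fa, miss = binary_collapse(cm, scheme)
    except ValueError:
        fa = miss = None
    return MetricsReport(
        confusion=cm,
        per_class=per,
        balanced_accuracy=ba,
        macro=macro,
        false_alarm_rate=fa,
        missed_cancer_rate=miss,
    )
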