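"""Evaluation metrics with balanced accuracy as the primary index.

Skin-lesion datasets are heavily imbalanced, so plain accuracy rewards
majority-class guessing.  The suite here therefore reports, alongside
accuracy, the macro one-vs-rest sensitivity TP/(TP+FN) and specificity
TN/(FP+TN) and their mean, the balanced accuracy

    BACC = (sensitivity + specificity) / 2,

plus macro one-vs-rest ROC-AUC.  The binary definitions extend to C
classes by treating each class against the rest and averaging unweighted,
which keeps BACC identical to the binary formula and invariant to class
prevalence.  A class with no true (resp. no non-true) samples is excluded
from the sensitivity (resp. specificity) average with a warning.

``bacc_recall`` (the mean recall reading of balanced accuracy, as used by
scikit-learn) is reported alongside ``bacc`` for comparability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix", "MetricsReport", "confusion", "accuracy",
    "sensitivity_specificity", "balanced_accuracy", "auc_macro",
    "compute_report", "plot_confusion",
]


@dataclass
class ConfusionMatrix:
    """Per-class counts; ``counts[i, j]`` = samples of true class i predicted j."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        C = len(self.classes)
        if self.counts.shape != (C, C):
            raise ValueError(f"confusion counts shape {self.counts.shape} != ({C}, {C})")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot merge confusion matrices over different classes")
        return ConfusionMatrix(self.counts + other.counts, self.classes)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.counts, index=list(self.classes),
                     columns=list(self.classes)).to_csv(path)


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    bacc: float
    bacc_recall: float
    auc: float | None
    per_class: dict = field(default_factory=dict)
    confusion: ConfusionMatrix | None = None

    def to_json(self) -> str:
        obj = {k: getattr(self, k) for k in
               ("accuracy", "sensitivity", "specificity", "bacc", "bacc_recall", "auc")}
        obj["per_class"] = self.per_class
        if self.confusion is not None:
            obj["confusion"] = self.confusion.counts.tolist()
            obj["classes"] = [str(c) for c in self.confusion.classes]
        return json.dumps(obj, indent=2)

    def summary(self) -> str:
        lines = [f"{'metric':<14}{'value':>8}"]
        for k in ("accuracy", "sensitivity", "specificity", "bacc", "auc"):
            v = getattr(self, k)
            lines.append(f"{k:<14}{v:>8.4f}" if v is not None else f"{k:<14}{'n/a':>8}")
        return "\n".join(lines)


def confusion(true_labels: Sequence, predicted_labels: Sequence,
              classes: Sequence) -> ConfusionMatrix:
    """Count each (true, predicted) pair over the declared class set."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"true label {t!r} not in declared classes {classes}")
        if p not in index:
            raise ValueError(f"predicted label {p!r} not in declared classes {classes}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def _require_nonempty(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ValueError("metric undefined on an empty confusion matrix")


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples: trace / total."""
    _require_nonempty(cm)
    return float(np.trace(cm.counts) / cm.total)


def _per_class_rates(cm: ConfusionMatrix):
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    tp = np.diag(counts)
    true_per_class = counts.sum(axis=1)
    pred_per_class = counts.sum(axis=0)
    fn = true_per_class - tp
    fp = pred_per_class - tp
    tn = total - tp - fn - fp
    return tp, fn, fp, tn, true_per_class


def sensitivity_specificity(cm: ConfusionMatrix) -> tuple[float, float]:
    """Macro one-vs-rest sensitivity and specificity.

    Classes whose rate is undefined (no true samples for sensitivity, no
    negatives for specificity) are dropped from the average with a warning.
    """
    _require_nonempty(cm)
    tp, fn, fp, tn, n_true = _per_class_rates(cm)
    sens_terms, spec_terms = [], []
    for i, c in enumerate(cm.classes):
        if tp[i] + fn[i] > 0:
            sens_terms.append(tp[i] / (tp[i] + fn[i]))
        else:
            warnings.warn(f"class {c!r} has no true samples; excluded from sensitivity")
        if fp[i] + tn[i] > 0:
            spec_terms.append(tn[i] / (fp[i] + tn[i]))
        else:
            warnings.warn(f"class {c!r} has no negative samples; excluded from specificity")
    if not sens_terms or not spec_terms:
        raise ValueError("sensitivity/specificity undefined: no valid class")
    return float(np.mean(sens_terms)), float(np.mean(spec_terms))


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """(macro sensitivity + macro specificity) / 2."""
    sens, spec = sensitivity_specificity(cm)
    return (sens + spec) / 2.0


def balanced_accuracy_recall(cm: ConfusionMatrix) -> float:
    """Mean per-class recall — the macro-recall reading of balanced accuracy."""
    _require_nonempty(cm)
    tp, fn, _, _, _ = _per_class_rates(cm)
    valid = (tp + fn) > 0
    return float((tp[valid] / (tp + fn)[valid]).mean())


def auc_macro(true_labels: Sequence, class_scores: np.ndarray,
              classes: Sequence) -> float:
    """Macro one-vs-rest ROC-AUC from per-class scores.

    Uses the rank (Mann-Whitney) formulation with ties counting 0.5; a
    class absent from the truth is excluded with a warning.
    """
    classes = tuple(classes)
    scores = np.asarray(class_scores, dtype=np.float64)
    y = np.asarray([list(classes).index(t) for t in true_labels])
    if scores.shape != (len(y), len(classes)):
        raise ValueError(f"score matrix shape {scores.shape} != {(len(y), len(classes))}")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    aucs = []
    for i, c in enumerate(classes):
        pos = y == i
        if pos.all() or not pos.any():
            warnings.warn(f"class {c!r} absent from truth (or is the only class); "
                          "excluded from AUC")
            continue
        aucs.append(roc_auc_score(pos.astype(int), scores[:, i]))
    if not aucs:
        raise ValueError("AUC undefined: no class has both positives and negatives")
    return float(np.mean(aucs))


def compute_report(true_labels: Sequence, predicted_labels: Sequence,
                   classes: Sequence, class_scores: np.ndarray | None = None,
                   ) -> MetricsReport:
    """Assemble the full evaluation report from labels and optional scores."""
    cm = confusion(true_labels, predicted_labels, classes)
    sens, spec = sensitivity_specificity(cm)
    tp, fn, fp, tn, _ = _per_class_rates(cm)
    per_class = {}
    for i, c in enumerate(cm.classes):
        per_class[str(c)] = {
            "sensitivity": float(tp[i] / (tp[i] + fn[i])) if tp[i] + fn[i] > 0 else None,
            "specificity": float(tn[i] / (fp[i] + tn[i])) if fp[i] + tn[i] > 0 else None,
            "support": int(tp[i] + fn[i]),
        }
    auc = None
    if class_scores is not None:
        auc = auc_macro(true_labels, class_scores, classes)
    return MetricsReport(
        accuracy=accuracy(cm),
        sensitivity=sens,
        specificity=spec,
        bacc=(sens + spec) / 2.0,
        bacc_recall=balanced_accuracy_recall(cm),
        auc=auc,
        per_class=per_class,
        confusion=cm,
    )


def plot_confusion(cm: ConfusionMatrix, ax=None, normalize: bool = False):
    """Render the confusion matrix as an annotated heatmap (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    counts = cm.counts.astype(float)
    if normalize:
        rowsum = counts.sum(axis=1, keepdims=True)
        counts = np.divide(counts, rowsum, out=np.zeros_like(counts), where=rowsum > 0)
    ax.imshow(counts, cmap="Blues")
    C = len(cm.classes)
    ax.set_xticks(range(C), [str(c) for c in cm.classes], rotation=45)
    ax.set_yticks(range(C), [str(c) for c in cm.classes])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(C):
        for j in range(C):
            ax.text(j, i, f"{counts[i, j]:.2f}" if normalize else f"{int(counts[i, j])}",
                    ha="center", va="center", fontsize=8)
    return ax
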