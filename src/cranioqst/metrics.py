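"""Dice coefficients, classification performance metrics and the CV harness.

Segmentation quality is summarised by the Dice coefficient
``2|A∩B| / (|A| + |B|)`` between a reference mask A and a predicted mask B,
computed per class over labels 1-6 (background excluded) and averaged.
Classifier quality is summarised one-vs-rest per QST type by sensitivity,
specificity, the Youden index (sensitivity + specificity - 1) and accuracy,
plus the overall 3-class accuracy, mirroring the usual side-by-side report
of a network against a clinical scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .label_schema import N_CLASSES, LabelMap, QSTType

__all__ = [
    "DiceReport",
    "ClassificationReport",
    "dice",
    "multiclass_dice",
    "classification_report",
    "make_cv_folds",
]


@dataclass
class DiceReport:
    """Per-class Dice for labels 1-6 plus their arithmetic mean."""

    per_class: dict[int, float]
    mean: float

    def to_frame(self) -> pd.DataFrame:
        from .label_schema import LABELS

        rows = [
            {"label": c, "tissue": LABELS[c], "dice": v} for c, v in self.per_class.items()
        ]
        rows.append({"label": "mean", "tissue": "mean (6 classes)", "dice": self.mean})
        return pd.DataFrame(rows)


@dataclass
class ClassificationReport:
    """One-vs-rest metrics per QST type and the overall 3-class accuracy."""

    confusion: np.ndarray  # 3x3, rows = true (Q,S,T), cols = predicted
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    youden: dict[str, float]
    accuracy: dict[str, float]
    overall_accuracy: float
    #: optional (n, 3) per-sample class probabilities (CV-aggregated)
    probabilities: np.ndarray | None = None

    TYPES = ("Q", "S", "T")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, values in [
            ("Sensitivity", self.sensitivity),
            ("Specificity", self.specificity),
            ("Youden index", self.youden),
            ("Accuracy", self.accuracy),
        ]:
            row = {"metric": metric}
            row.update({t: values[t] for t in self.TYPES})
            row["3type"] = self.overall_accuracy if metric == "Accuracy" else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def dice(a: np.ndarray, b: np.ndarray, *, empty_value: float = 1.0) -> float:
    """Dice coefficient ``2|A∩B| / (|A| + |B|)`` between two binary masks.

    Symmetric in its arguments.  When both masks are empty the coefficient is
    undefined by the formula; by default it is reported as ``empty_value``
    (1.0), so that a class legitimately absent from both reference and
    prediction — the suprasellar cistern can be effaced entirely — is not
    penalised.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return float(empty_value)
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def multiclass_dice(
    pred: LabelMap, ref: LabelMap, *, empty_value: float = 1.0
) -> DiceReport:
    """Per-class Dice for labels 1-6 and their mean; background is excluded."""
    if pred.shape != ref.shape:
        raise ValueError(f"shapes differ: {pred.shape} vs {ref.shape}")
    per_class = {
        c: dice(pred.voxels == c, ref.voxels == c, empty_value=empty_value)
        for c in range(1, N_CLASSES)
    }
    return DiceReport(per_class=per_class, mean=float(np.mean(list(per_class.values()))))


def classification_report(y_true, y_pred) -> ClassificationReport:
    """One-vs-rest sensitivity/specificity/Youden/accuracy per QST type.

    Built from the 3x3 confusion matrix (rows = true, columns = predicted,
    both ordered Q, S, T); the overall accuracy is its trace over the total.
    """
    y_true = [QSTType(t) for t in y_true]
    y_pred = [QSTType(t) for t in y_pred]
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    types = ClassificationReport.TYPES
    idx = {t: i for i, t in enumerate(types)}
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    n = cm.sum()
    sens, spec, youden, acc = {}, {}, {}, {}
    for t, i in idx.items():
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens[t] = tp / (tp + fn) if tp + fn else float("nan")
        spec[t] = tn / (tn + fp) if tn + fp else float("nan")
        youden[t] = sens[t] + spec[t] - 1.0
        acc[t] = (tp + tn) / n
    return ClassificationReport(
        confusion=cm,
        sensitivity=sens,
        specificity=spec,
        youden=youden,
        accuracy=acc,
        overall_accuracy=float(np.trace(cm)) / n,
    )


def make_cv_folds(n: int, k: int = 5, labels=None, seed: int = 0) -> list[np.ndarray]:
    """k disjoint test-index sets partitioning ``range(n)``, sizes differing by <= 1.

    With ``labels`` given the folds are stratified per type, so each fold
    preserves the cohort's type proportions to within one sample.  Shuffling
    is reproducible from ``seed``.
    """
    if not (2 <= k <= n):
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    if labels is not None:
        if len(labels) != n:
            raise ValueError("labels length must equal n")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_args = (np.zeros(n), np.asarray([str(l) for l in labels]))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_args = (np.zeros(n),)
    return [test_idx for _, test_idx in splitter.split(*split_args)]
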