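"""Evaluation metrics: per-class precision/recall/F1, confusion matrices,
and cumulative band-contribution summaries.

Per class c (one-vs-rest counts from the confusion matrix):

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Overall accuracy is micro accuracy, trace(confusion) / total. Undefined
ratios (empty denominators) are reported as 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ClassificationReport:
    """Per-class P/R/F1 with confusion matrix and micro overall accuracy."""

    classes: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    confusion: np.ndarray
    overall_accuracy: float

    def to_dataframe(self, decimals: int = 4) -> pd.DataFrame:
        """Table-shaped report: one row per class plus the overall accuracy."""
        df = pd.DataFrame({
            "class": self.classes,
            "precision": np.round(self.precision, decimals),
            "recall": np.round(self.recall, decimals),
            "f1": np.round(self.f1, decimals),
            "support": self.support,
        })
        df.attrs["overall_accuracy"] = round(self.overall_accuracy, decimals)
        return df

    def to_dict(self, decimals: int = 4) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "precision": [round(float(v), decimals) for v in self.precision],
            "recall": [round(float(v), decimals) for v in self.recall],
            "f1": [round(float(v), decimals) for v in self.f1],
            "support": [int(v) for v in self.support],
            "confusion": self.confusion.tolist(),
            "overall_accuracy": round(float(self.overall_accuracy), decimals),
        }


def classification_report(truth, pred, classes=None) -> ClassificationReport:
    """Compute the per-class report for predicted vs true labels.

    ``classes`` fixes the class order (default: sorted union of labels).
    A class that never occurs in truth or prediction gets P = R = F1 = 0
    with a warning.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(
            f"length mismatch: {truth.shape[0]} true vs {pred.shape[0]} predicted labels"
        )
    if classes is None:
        classes = np.unique(np.concatenate([truth, pred]))
    else:
        classes = np.asarray(classes)
        seen = set(np.unique(np.concatenate([truth, pred])).tolist())
        missing = seen - set(classes.tolist())
        if missing:
            raise ValueError(f"labels outside the class set: {sorted(missing)}")
    cm = confusion_matrix(truth, pred, labels=classes)
    absent = (cm.sum(axis=0) + cm.sum(axis=1)) == 0
    if absent.any():
        warnings.warn(
            f"classes never observed nor predicted: {classes[absent].tolist()}; "
            "their metrics are reported as 0",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division handled by policy below
        p, r, f1, support = precision_recall_fscore_support(
            truth, pred, labels=classes, zero_division=0)
    overall = float(np.trace(cm) / cm.sum())
    return ClassificationReport(classes, p, r, f1, support, cm, overall)


def cumulative_contribution(importances, k: int) -> float:
    """Sum of the ``k`` largest band importances ("cumulative contribution rate")."""
    imp = np.asarray(importances, dtype=float)
    if np.any(imp < 0):
        raise ValueError("importances must be non-negative")
    if not 1 <= k <= imp.size:
        raise ValueError(f"k must be in [1, {imp.size}]")
    return float(np.sort(imp)[::-1][:k].sum())


@dataclass
class ImportanceReport:
    """Band importances with descending ranking and top-k contribution sums."""

    importances: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.importances = np.asarray(self.importances, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.importances.shape != self.wavelengths.shape:
            raise ValueError("importances and wavelengths must align")
        if np.any(self.importances < 0):
            raise ValueError("importances must be non-negative")

    @property
    def ranking(self) -> np.ndarray:
        """Band indices sorted by descending importance (stable)."""
        return np.argsort(-self.importances, kind="stable")

    def top_k(self, k: int) -> pd.DataFrame:
        idx = self.ranking[:k]
        return pd.DataFrame({
            "band": idx,
            "wavelength_nm": self.wavelengths[idx],
            "importance": self.importances[idx],
        })

    def cumulative(self, k: int) -> float:
        return cumulative_contribution(self.importances, k)
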