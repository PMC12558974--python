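"""Classification and regression metrics plus a model-comparison harness.

Classification metrics follow the standard confusion-matrix definitions:
specificity TN/(TN+FP), accuracy (TP+TN)/total, precision TP/(TP+FP),
recall TP/(TP+FN), F1 = 2PR/(P+R). Regression metrics: MSE and
R² = 1 − SS_res/SS_tot. A zero denominator yields an explicit ``None``
(undefined) rather than a silent zero, so degenerate classifiers are
visible in comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_labels",
    "classification_metrics",
    "regression_metrics",
    "compare_models",
    "binarize_severity",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DomainError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    specificity: float | None = None
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    mse: float | None = None
    r2: float | None = None
    n: int = 0

    def as_dict(self) -> dict:
        return {"specificity": self.specificity, "accuracy": self.accuracy,
                "precision": self.precision, "recall": self.recall, "f1": self.f1,
                "mse": self.mse, "r2": self.r2, "n": self.n}


def binarize_severity(labels: Sequence[str], strict: bool = False) -> np.ndarray:
    """Map severity labels to binary anomaly indicators.

    Default: anomaly = mild or severe. Strict mode: anomaly = severe only.
    """
    positive = {"severe"} if strict else {"mild", "severe"}
    out = []
    for lab in labels:
        if lab not in ("normal", "mild", "severe"):
            raise ContractError(f"unknown severity label {lab!r}")
        out.append(lab in positive)
    return np.array(out, dtype=bool)


def confusion_from_labels(truth, predicted) -> ConfusionCounts:
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ContractError("truth and predicted lengths differ")
    return ConfusionCounts(
        tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)))


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Specificity, accuracy, precision, recall and F1 from counts."""
    if counts.total == 0:
        raise DomainError("confusion counts sum to zero")
    precision = _safe_div(counts.tp, counts.tp + counts.fp)
    recall = _safe_div(counts.tp, counts.tp + counts.fn)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        specificity=_safe_div(counts.tn, counts.tn + counts.fp),
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=precision, recall=recall, f1=f1, n=counts.total)


def regression_metrics(actual, predicted) -> tuple[float, float | None]:
    """(MSE, R²); R² is None when the actual values have zero variance."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ContractError("actual and predicted lengths differ")
    if y.size < 2:
        raise ContractError("need at least 2 points")
    mse = float(np.mean((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return mse, None
    ss_res = float(np.sum((y - yhat) ** 2))
    return mse, 1.0 - ss_res / ss_tot


def compare_models(results: Mapping[str, Sequence], truth: Sequence,
                   kind: str = "classification", strict: bool = False) -> pd.DataFrame:
    """One metrics row per named model, aligned against a shared truth.

    ``kind="classification"`` expects boolean or severity-label vectors;
    ``kind="regression"`` expects numeric predictions.
    """
    rows = {}
    truth_arr = np.asarray(truth)
    for name, preds in results.items():
        preds_arr = np.asarray(preds)
        if len(preds_arr) != len(truth_arr):
            raise ContractError(f"model {name!r}: predictions misaligned with truth")
        if kind == "classification":
            t = (binarize_severity(truth_arr, strict) if truth_arr.dtype.kind == "U"
                 else truth_arr.astype(bool))
            p = (binarize_severity(preds_arr, strict) if preds_arr.dtype.kind == "U"
                 else preds_arr.astype(bool))
            report = classification_metrics(confusion_from_labels(t, p))
        elif kind == "regression":
            mse, r2 = regression_metrics(truth_arr.astype(float), preds_arr.astype(float))
            report = MetricsReport(mse=mse, r2=r2, n=len(truth_arr))
        else:
            raise ContractError(f"unknown kind {kind!r}")
        rows[name] = report.as_dict()
    return pd.DataFrame.from_dict(rows, orient="index")
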