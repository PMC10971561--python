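"""Confusion-matrix evaluation: overall accuracy, Cohen's Kappa, UA/PA.

The confusion matrix is oriented rows = predicted, columns = actual, so
user accuracy (UA, commission) is the row-wise diagonal fraction and
producer accuracy (PA, omission) the column-wise one. Overall accuracy
is trace/S — the multiclass form of the binary (TP+TN)/(TP+TN+FP+FN) —
and Kappa is (OA - p_e)/(1 - p_e) with chance agreement
p_e = sum_c N_p(c) * N_t(c) / S^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "overall_accuracy",
    "kappa",
    "class_accuracies",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k counts; rows = predicted class, columns = actual class."""

    C: np.ndarray
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        C = np.asarray(self.C)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        if C.shape[0] != len(self.labels):
            raise ValueError("labels must match matrix dimension")
        if np.any(C < 0):
            raise ValueError("counts must be non-negative")

    @property
    def S(self) -> int:
        return int(self.C.sum())

    @property
    def N_p(self) -> np.ndarray:  # predicted totals (row sums)
        return self.C.sum(axis=1)

    @property
    def N_t(self) -> np.ndarray:  # actual totals (column sums)
        return self.C.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C,
                            index=[f"pred_{l}" for l in self.labels],
                            columns=[f"actual_{l}" for l in self.labels])


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int],
                     labels: Sequence[int] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = tuple(int(l) for l in labels)
    pos = {l: i for i, l in enumerate(labels)}
    C = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        C[pos[int(p)], pos[int(t)]] += 1  # rows = predicted
    return ConfusionMatrix(C=C, labels=labels)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Agreement fraction trace(C)/S."""
    if cm.S == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.C) / cm.S)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's Kappa; NaN sentinel when chance agreement p_e = 1."""
    S = cm.S
    if S == 0:
        raise ValueError("empty confusion matrix")
    oa = overall_accuracy(cm)
    p_e = float((cm.N_p * cm.N_t).sum() / S**2)
    if p_e >= 1.0:
        return float("nan")  # single class on both axes: undefined
    return (oa - p_e) / (1.0 - p_e)


def class_accuracies(cm: ConfusionMatrix) -> tuple[dict[int, float],
                                                   dict[int, float]]:
    """(UA, PA) per class; zero-margin classes report NaN."""
    diag = np.diag(cm.C).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(cm.N_p > 0, diag / np.maximum(cm.N_p, 1), np.nan)
        ua = np.where(cm.N_p > 0, ua, np.nan)
        pa = np.where(cm.N_t > 0, diag / np.maximum(cm.N_t, 1), np.nan)
        pa = np.where(cm.N_t > 0, pa, np.nan)
    return ({l: float(u) for l, u in zip(cm.labels, ua)},
            {l: float(p) for l, p in zip(cm.labels, pa)})


@dataclass
class EvaluationReport:
    """One model evaluation: matrix, OA, Kappa, UA/PA, importances, meta."""

    cm: ConfusionMatrix
    OA: float
    Kappa: float
    UA: dict[int, float]
    PA: dict[int, float]
    importances: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.OA <= 1.0):
            raise ValueError("OA must lie in [0, 1]")
        if np.isfinite(self.Kappa) and not (-1.0 <= self.Kappa <= 1.0 + 1e-12):
            raise ValueError("Kappa must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.cm.C.tolist(),
            "labels": list(self.cm.labels),
            "orientation": "rows=predicted, columns=actual",
            "OA": self.OA,
            "Kappa": self.Kappa,
            "UA": {str(k): v for k, v in self.UA.items()},
            "PA": {str(k): v for k, v in self.PA.items()},
            "importances": self.importances,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def __str__(self) -> str:
        lines = [self.cm.to_frame().to_string(),
                 f"OA = {self.OA:.4f}   Kappa = {self.Kappa:.4f}"]
        for l in self.cm.labels:
            lines.append(f"  level {l}: UA = {self.UA[l]:.4f}  "
                         f"PA = {self.PA[l]:.4f}")
        return "\n".join(lines)


def evaluate_predictions(y_true: Sequence[int], y_pred: Sequence[int],
                         labels: Sequence[int] | None = None,
                         importances: Mapping[str, float] | None = None,
                         metadata: Mapping | None = None) -> EvaluationReport:
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    ua, pa = class_accuracies(cm)
    return EvaluationReport(cm=cm, OA=overall_accuracy(cm), Kappa=kappa(cm),
                            UA=ua, PA=pa,
                            importances=dict(importances or {}),
                            metadata=dict(metadata or {}))
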