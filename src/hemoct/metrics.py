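"""Confusion matrices and the sensitivity / precision / F1 / AUC suite.

The confusion matrix orientation is fixed: rows are predicted classes and
columns are actual classes. For class ``c``: TP is the diagonal entry, FP is
the rest of row ``c`` (predicted c, actually something else), FN the rest of
column ``c``. Sensitivity S = TP/(TP+FN), precision P = TP/(TP+FP), and
F1 = 2 / (1/S + 1/P), the harmonic mean. The overall score is the
micro-average, trace/total, which for single-label multi-class problems
equals accuracy; the macro average (unweighted mean of defined per-class F1s)
is also reported. Metrics with a zero denominator are returned as NaN with a
warning — never silently as 0.

AUC is the Mann-Whitney rank statistic: the fraction of (positive, negative)
pairs ordered correctly, ties counted one half. This equals the trapezoidal
area under the ROC curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import MetricsError

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "roc_auc",
]


@dataclass
class ConfusionMatrix:
    """K x K counts; ``counts[i, j]`` = predicted ``labels[i]``, actual ``labels[j]``."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.labels = tuple(str(l) for l in self.labels)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.labels, name="predicted"),
            columns=pd.Index(self.labels, name="actual"),
        )

    def to_csv(self, path) -> Path:
        self.to_frame().to_csv(path)
        return Path(path)


@dataclass
class ClassMetrics:
    sensitivity: float
    precision: float
    f1: float


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    micro_f1: float
    macro_f1: float
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "per_class": {
                k: {"sensitivity": m.sensitivity, "precision": m.precision, "f1": m.f1}
                for k, m in self.per_class.items()
            },
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "auc": self.auc,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def confusion_matrix(
    true_labels: Sequence, predicted_labels: Sequence, labels: Sequence
) -> ConfusionMatrix:
    """Count predictions into the fixed rows-predicted / columns-actual layout."""
    true_labels = [str(t) for t in true_labels]
    predicted_labels = [str(p) for p in predicted_labels]
    labels = tuple(str(l) for l in labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts, labels)


def _safe_ratio(num: float, den: float, what: str, label: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {label!r} (zero denominator)")
        return float("nan")
    return num / den


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class sensitivity/precision/F1 plus micro and macro aggregates."""
    counts = cm.counts
    total = int(counts.sum())
    if total == 0:
        raise MetricsError("all-zero confusion matrix")
    per_class: dict[str, ClassMetrics] = {}
    f1s = []
    for i, label in enumerate(cm.labels):
        tp = float(counts[i, i])
        fp = float(counts[i, :].sum() - tp)
        fn = float(counts[:, i].sum() - tp)
        sens = _safe_ratio(tp, tp + fn, "sensitivity", label)
        prec = _safe_ratio(tp, tp + fp, "precision", label)
        if np.isnan(sens) or np.isnan(prec) or sens + prec == 0:
            if not (np.isnan(sens) or np.isnan(prec)):
                warnings.warn(f"F1 undefined for class {label!r} (S + P = 0)")
            f1 = float("nan")
        else:
            f1 = 2.0 * sens * prec / (sens + prec)
            f1s.append(f1)
        per_class[label] = ClassMetrics(sens, prec, f1)
    micro = float(np.trace(counts)) / total
    macro = float(np.mean(f1s)) if f1s else float("nan")
    return MetricsReport(per_class=per_class, micro_f1=micro, macro_f1=macro)


def roc_auc(scores: Sequence[float], truths: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(random positive scores above random negative).

    ``truths`` are 0/1 (or booleans); ties in score count one half. Raises
    :class:`MetricsError` if either class is absent.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths).astype(bool)
    n_pos = int(truths.sum())
    n_neg = int((~truths).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricsError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # mid-ranks handle ties as 1/2
    u = ranks[truths].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
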