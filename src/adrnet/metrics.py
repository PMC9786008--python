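"""Multi-label evaluation: accuracy, macro precision/recall, macro AUC/AUPR.

Conventions, fixed once and used everywhere:

* **Accuracy** is sample-wise label (Hamming) accuracy: for each sample,
  the fraction of its labels predicted correctly, averaged over samples.
* **Macro precision / recall** pool TP/FP/FN counts per label over all
  samples, compute the per-label ratio, and average over labels whose
  denominator is nonzero. Labels with undefined ratios are excluded from
  the mean and reported, never silently counted as zero.
* **Macro AUC / AUPR** are per-label ROC-AUC and average precision
  (scikit-learn), averaged over labels with both classes present;
  single-class labels are excluded and reported. Ties in scores contribute
  0.5 per pair to AUC (Mann-Whitney convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import ConfigurationError

__all__ = [
    "accuracy",
    "macro_precision",
    "macro_recall",
    "macro_auc",
    "macro_aupr",
    "evaluate",
    "MetricsReport",
]


def _check_shapes(truth, other) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth)
    o = np.asarray(other)
    if t.shape != o.shape:
        raise ConfigurationError(
            f"shape mismatch: truth {t.shape} vs predictions {o.shape}"
        )
    if t.ndim != 2:
        raise ConfigurationError("expected 2-D (samples x labels) matrices")
    return t, o


def accuracy(truth, pred) -> float:
    """Sample-wise Hamming accuracy averaged over samples."""
    t, p = _check_shapes(truth, pred)
    return float((t == p).mean(axis=1).mean())


def _pooled_counts(t: np.ndarray, p: np.ndarray):
    tp = ((t == 1) & (p == 1)).sum(axis=0)
    fp = ((t == 0) & (p == 1)).sum(axis=0)
    fn = ((t == 1) & (p == 0)).sum(axis=0)
    return tp, fp, fn


def _macro_ratio(num: np.ndarray, den: np.ndarray) -> tuple[float, np.ndarray, list[int]]:
    per_label = np.full(len(den), np.nan)
    defined = den > 0
    per_label[defined] = num[defined] / den[defined]
    excluded = [int(i) for i in np.flatnonzero(~defined)]
    value = float(per_label[defined].mean()) if defined.any() else float("nan")
    return value, per_label, excluded


def macro_precision(truth, pred) -> float:
    t, p = _check_shapes(truth, pred)
    tp, fp, _ = _pooled_counts(t, p)
    value, _, _ = _macro_ratio(tp, tp + fp)
    return value


def macro_recall(truth, pred) -> float:
    t, p = _check_shapes(truth, pred)
    tp, _, fn = _pooled_counts(t, p)
    value, _, _ = _macro_ratio(tp, tp + fn)
    return value


def _per_label_ranking(truth: np.ndarray, scores: np.ndarray, fn):
    values = np.full(truth.shape[1], np.nan)
    excluded: list[int] = []
    for j in range(truth.shape[1]):
        col = truth[:, j]
        if col.min() == col.max():  # single-class label: metric undefined
            excluded.append(j)
            continue
        values[j] = fn(col, scores[:, j])
    defined = ~np.isnan(values)
    mean = float(values[defined].mean()) if defined.any() else float("nan")
    return mean, values, excluded


def macro_auc(truth, scores) -> float:
    t, s = _check_shapes(truth, scores)
    value, _, _ = _per_label_ranking(t, s, roc_auc_score)
    return value


def macro_aupr(truth, scores) -> float:
    t, s = _check_shapes(truth, scores)
    value, _, _ = _per_label_ranking(t, s, average_precision_score)
    return value


@dataclass
class MetricsReport:
    """The five headline metrics plus the per-label breakdown behind them."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_auc: float
    macro_aupr: float
    per_label: pd.DataFrame
    excluded: dict[str, list] = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_auc": self.macro_auc,
            "macro_aupr": self.macro_aupr,
        }

    def to_text(self) -> str:
        buf = StringIO()
        for name, value in self.summary().items():
            buf.write(f"{name}: {value:.4f}\n")
        for metric, labels in self.excluded.items():
            if labels:
                buf.write(f"excluded from {metric}: {labels}\n")
        return buf.getvalue()

    def to_csv(self, path) -> None:
        self.per_label.to_csv(path, index_label="label")


def evaluate(truth, scores, threshold: float = 0.5, label_names=None) -> MetricsReport:
    """Full evaluation: binarize scores at ``threshold`` (>= rule) for the
    count-based metrics, use raw scores for AUC/AUPR."""
    t, s = _check_shapes(truth, scores)
    pred = (s >= threshold).astype(int)
    tp, fp, fn = _pooled_counts(t, pred)
    prec, prec_per_label, prec_excl = _macro_ratio(tp, tp + fp)
    rec, rec_per_label, rec_excl = _macro_ratio(tp, tp + fn)
    auc, auc_per_label, auc_excl = _per_label_ranking(t, s, roc_auc_score)
    aupr, aupr_per_label, aupr_excl = _per_label_ranking(
        t, s, average_precision_score
    )
    if label_names is None:
        label_names = [f"label_{j}" for j in range(t.shape[1])]
    name = {j: label_names[j] for j in range(t.shape[1])}
    per_label = pd.DataFrame(
        {
            "positives": t.sum(axis=0),
            "precision": prec_per_label,
            "recall": rec_per_label,
            "auc": auc_per_label,
            "aupr": aupr_per_label,
        },
        index=pd.Index(label_names, name="label"),
    )
    return MetricsReport(
        accuracy=accuracy(t, pred),
        macro_precision=prec,
        macro_recall=rec,
        macro_auc=auc,
        macro_aupr=aupr,
        per_label=per_label,
        excluded={
            "precision": [name[j] for j in prec_excl],
            "recall": [name[j] for j in rec_excl],
            "auc": [name[j] for j in auc_excl],
            "aupr": [name[j] for j in aupr_excl],
        },
    )
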