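"""Confusion-matrix statistics and ROC/AUC evaluation.

The four primary statistics are the standard sensitivity, specificity,
accuracy and Matthews correlation coefficient:

.. math::

    Sn  &= TP / (TP + FN) \\\\
    Sp  &= TN / (TN + FP) \\\\
    Acc &= (TP + TN) / (TP + FP + TN + FN) \\\\
    MCC &= \\frac{TP \\cdot TN - FP \\cdot FN}
                {\\sqrt{(TP+FN)(TN+FP)(TP+FP)(TN+FN)}}

AUC is computed exactly from continuous decision scores via the rank
(Mann–Whitney U) formulation, with ties contributing 1/2 — the probability
that a random positive scores above a random negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix cell counts (label 1 = positive)."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity, specificity, accuracy, MCC and (optionally) AUC.

    Any statistic whose denominator is zero is reported as 0.0 and its name
    recorded in ``degenerate`` rather than raising.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float | None = None
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "Accuracy": self.accuracy,
            "MCC": self.mcc,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        return d

    def __str__(self) -> str:
        parts = [f"{k}={v:.4f}" for k, v in self.as_dict().items()]
        if self.degenerate:
            parts.append(f"degenerate={','.join(self.degenerate)}")
        return "MetricsReport(" + ", ".join(parts) + ")"


def confusion(labels, predictions) -> ConfusionCounts:
    """Count TP/FP/TN/FN from parallel binary vectors (1 = positive)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if y.size and (not np.isin(y, (0, 1)).all() or not np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionCounts(
        TP=int(((y == 1) & (p == 1)).sum()),
        FP=int(((y == 0) & (p == 1)).sum()),
        TN=int(((y == 0) & (p == 0)).sum()),
        FN=int(((y == 1) & (p == 0)).sum()),
    )


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Derive Sn/Sp/Acc/MCC from confusion counts (zero denominators flagged)."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    flags: list[str] = []
    sn = _safe_div(tp, tp + fn, "sensitivity", flags)
    sp = _safe_div(tn, tn + fp, "specificity", flags)
    acc = _safe_div(tp + tn, counts.total, "accuracy", flags)
    mcc_den = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc", flags)
    return MetricsReport(
        sensitivity=sn, specificity=sp, accuracy=acc, mcc=mcc, auc=auc,
        degenerate=tuple(flags),
    )


class UndefinedAUCError(ValueError):
    """Raised when AUC is requested for single-class labels."""


def roc_auc(labels, scores) -> float:
    """Exact AUC by the normalized Mann–Whitney U statistic (ties count 1/2)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined: {n_pos} positives, {n_neg} negatives"
        )
    ranks = rankdata(s)  # average ranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_predictions(labels, predictions, scores=None) -> MetricsReport:
    """One-call evaluation: confusion counts -> metrics, plus AUC if scores given."""
    auc = roc_auc(labels, scores) if scores is not None else None
    return compute_metrics(confusion(labels, predictions), auc=auc)


def report_table(reports: dict[str, MetricsReport]):
    """One-row-per-model table with Sensitivity/Specificity/Accuracy/MCC/AUC columns."""
    import pandas as pd

    rows = []
    for name, rep in reports.items():
        row = {"Model": name, **rep.as_dict()}
        row.setdefault("AUC", float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=["Model", "Sensitivity", "Specificity", "Accuracy", "MCC", "AUC"])
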