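"""Benchmark metrics for differential-distribution calls on labeled data.

A gene is called positive when its p-value is at or below the threshold
(<=, consistent with the discrete support of permutation p-values).
Ratios with empty denominators (e.g. specificity when every gene is truly
DD) are reported as ``None`` rather than 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .simulate import DD_CATEGORIES

__all__ = [
    "EvaluationReport",
    "confusion_metrics",
    "roc_auc",
    "per_category_power",
    "evaluate_calls",
]


def _check_lengths(*arrays):
    sizes = {np.asarray(a).shape[0] for a in arrays}
    if len(sizes) != 1:
        raise ValueError("input vectors must have equal length")


def confusion_metrics(pvals, is_dd, threshold: float = 0.05):
    """(sensitivity, specificity, precision, accuracy) at a p threshold."""
    p = np.asarray(pvals, dtype=float)
    y = np.asarray(is_dd, dtype=bool)
    _check_lengths(p, y)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    call = p <= threshold
    tp = int(np.sum(call & y))
    fp = int(np.sum(call & ~y))
    fn = int(np.sum(~call & y))
    tn = int(np.sum(~call & ~y))

    div = lambda a, b: a / b if b > 0 else None
    return (
        div(tp, tp + fn),
        div(tn, tn + fp),
        div(tp, tp + fp),
        div(tp + tn, tp + fp + fn + tn),
    )


def roc_auc(pvals, is_dd):
    """ROC points (FPR, TPR) and trapezoidal AUC, scoring genes by -p."""
    p = np.asarray(pvals, dtype=float)
    y = np.asarray(is_dd, dtype=bool)
    _check_lengths(p, y)
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, -p)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def per_category_power(pvals, labels, threshold: float = 0.05) -> dict[str, float]:
    """Detection power (sensitivity) per DD category present in ``labels``."""
    p = np.asarray(pvals, dtype=float)
    lab = np.asarray(labels)
    _check_lengths(p, lab)
    power = {}
    for cat in DD_CATEGORIES:
        m = lab == cat
        if m.any():
            power[cat] = float(np.mean(p[m] <= threshold))
    return power


@dataclass
class EvaluationReport:
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    auc: float
    roc_points: list[tuple[float, float]]
    power_by_category: dict[str, float]
    threshold: float
    n_genes: int

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    def roc_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(
            path, sep="\t", index=False)


def evaluate_calls(pvals, labels, threshold: float = 0.05) -> EvaluationReport:
    """Full benchmark report from per-gene p-values and true categories."""
    lab = np.asarray(labels)
    is_dd = np.isin(lab, DD_CATEGORIES)
    sens, spec, prec, acc = confusion_metrics(pvals, is_dd, threshold)
    points, auc_val = roc_auc(pvals, is_dd)
    return EvaluationReport(
        sensitivity=sens, specificity=spec, precision=prec, accuracy=acc,
        auc=auc_val, roc_points=points,
        power_by_category=per_category_power(pvals, lab, threshold),
        threshold=threshold, n_genes=int(lab.size),
    )
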