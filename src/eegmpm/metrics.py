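"""Evaluation metrics: one-vs-rest confusion counts, SEN/SPE/ACC, ROC.

SEN = TP/(TP+FN), SPE = TN/(TN+FP), ACC = (TP+TN)/(TP+FP+TN+FN), computed
one-vs-rest per class for multiclass problems (plus macro averages and an
overall ACC).  Metrics with a zero denominator are reported as ``None``,
never silently 0.

The ROC curve is a threshold sweep over the unique decision scores
(w'z - b margins), area by the trapezoid rule; the curve always starts at
(0, 0) and ends at (1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ShapeError


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion table for a single positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(
    y_true: Sequence, y_pred: Sequence, positive
) -> ConfusionCounts:
    """Count TP/FP/TN/FN treating ``positive`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ShapeError(
            f"label sequences differ in length: {y_true.shape} vs {y_pred.shape}"
        )
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def sen_spe_acc(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(SEN, SPE, ACC); any metric with a zero denominator is ``None``."""
    sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = (c.tp + c.tn) / c.total if c.total > 0 else None
    return sen, spe, acc


@dataclass(frozen=True)
class RocCurve:
    """Ordered ROC points plus trapezoid area.

    ``thresholds`` holds the score cut for each point after the forced
    (0, 0) start (its first entry is +inf).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], y_true: Sequence[int]) -> RocCurve:
    """Threshold sweep of ``score >= t -> positive`` over unique scores.

    ``y_true`` must be binary (0/1 or bool) with both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true).astype(bool)
    if scores.shape != y.shape:
        raise ShapeError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_y = y[order]
    # step through distinct thresholds, cumulative counts at each
    tp = np.cumsum(sorted_y)
    fp = np.cumsum(~sorted_y)
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.r_[distinct, sorted_scores.size - 1]
    fpr = np.r_[0.0, fp[idx] / n_neg]
    tpr = np.r_[0.0, tp[idx] / n_pos]
    thresholds = np.r_[np.inf, sorted_scores[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, thresholds, auc)


def per_class_report(
    y_true: Sequence, y_pred: Sequence, classes: Sequence | None = None
) -> pd.DataFrame:
    """Per-class one-vs-rest SEN/SPE plus macro averages and overall ACC.

    Mirrors the usual per-group reporting: one row per class, then a
    ``macro`` row averaging the defined entries, then an ``overall`` row
    whose ACC is the plain multiclass accuracy.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true.tolist()))
    rows = []
    sens, spes = [], []
    for c in classes:
        sen, spe, _ = sen_spe_acc(confusion_counts(y_true, y_pred, c))
        rows.append({"class": c, "SEN": sen, "SPE": spe})
        if sen is not None:
            sens.append(sen)
        if spe is not None:
            spes.append(spe)
    rows.append(
        {
            "class": "macro",
            "SEN": float(np.mean(sens)) if sens else None,
            "SPE": float(np.mean(spes)) if spes else None,
        }
    )
    overall_acc = float(np.mean(y_true == y_pred)) if y_true.size else None
    rows.append({"class": "overall", "SEN": None, "SPE": None})
    df = pd.DataFrame(rows, columns=["class", "SEN", "SPE"])
    df["ACC"] = [None] * (len(rows) - 1) + [overall_acc]
    return df


def write_metrics_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def write_roc_csv(curve: RocCurve, path) -> None:
    pd.DataFrame(
        {"threshold": curve.thresholds, "FPR": curve.fpr, "TPR": curve.tpr}
    ).to_csv(path, index=False, float_format="%.17g")
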