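"""Evaluation metrics, McNemar's paired test, and threshold-free curves.

Metric conventions
------------------
Sp = TN/(TN+FP), Sn = TP/(TP+FN), Acc = (TP+TN)/all, Pre = TP/(TP+FP),
F1 = 2*Pre*Sn/(Pre+Sn). In the lncRNA/mRNA literature these five are
often reported with Sp and Sn read as the per-class accuracies of lncRNA
and mRNA respectively — i.e. TP is counted on the *mRNA* class even when
lncRNA is the training-positive class. :func:`report` therefore defaults
``positive_class="mRNA"`` and additionally labels the per-class
accuracies by class name to remove the ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class MetricsReport:
    """Confusion counts and the five derived metrics for one prediction set."""

    tp: int
    fn: int
    tn: int
    fp: int
    sp: float
    sn: float
    acc: float
    pre: float
    f1: float
    positive_class: str = ""

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sp": self.sp, "sn": self.sn, "acc": self.acc,
            "pre": self.pre, "f1": self.f1,
            "positive_class": self.positive_class,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(
    y_true: Sequence, y_pred: Sequence, positive_class
) -> MetricsReport:
    """Confusion counts and Sp/Sn/Acc/Pre/F1 under the given positive class.

    F1 is defined as 0 when Pre + Sn = 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    t = y_true == positive_class
    p = y_pred == positive_class
    tp = int(np.sum(t & p))
    fn = int(np.sum(t & ~p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    sp = _safe_div(tn, tn + fp)
    sn = _safe_div(tp, tp + fn)
    acc = _safe_div(tp + tn, tp + fn + tn + fp)
    pre = _safe_div(tp, tp + fp)
    f1 = _safe_div(2.0 * pre * sn, pre + sn)
    return MetricsReport(tp=tp, fn=fn, tn=tn, fp=fp, sp=sp, sn=sn, acc=acc,
                         pre=pre, f1=f1, positive_class=str(positive_class))


def report(
    y_true: Sequence, y_pred: Sequence,
    positive_class: str = "mRNA",
    lncRNA_label: str = "lncRNA",
    mRNA_label: str = "mRNA",
) -> dict:
    """Metrics dict with per-class accuracies labelled by class name."""
    m = compute_metrics(y_true, y_pred, positive_class)
    out = m.to_dict()
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    for cls in (lncRNA_label, mRNA_label):
        mask = y_true == cls
        out[f"acc_{cls}"] = float(np.mean(y_pred[mask] == cls)) if mask.any() else float("nan")
    return out


@dataclass
class McNemarResult:
    """Discordant-pair counts and the continuity-corrected chi-square test."""

    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    chi2: float
    p_value: float


def mcnemar_test(correct_a: Sequence[bool], correct_b: Sequence[bool]) -> McNemarResult:
    """Continuity-corrected McNemar test on paired correctness vectors.

    chi2 = (|b - c| - 1)^2 / (b + c), floored at 0 when b + c = 0 or
    |b - c| <= 1; the p-value is the upper tail of chi-square with 1 df.
    """
    a = np.asarray(correct_a, dtype=bool)
    bvec = np.asarray(correct_b, dtype=bool)
    if a.shape != bvec.shape:
        raise ValueError("correctness vectors must have equal length")
    b = int(np.sum(a & ~bvec))
    c = int(np.sum(~a & bvec))
    if b + c == 0 or abs(b - c) <= 1:
        chi2 = 0.0
    else:
        chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
    p = float(chi2_dist.sf(chi2, df=1))
    return McNemarResult(b=b, c=c, chi2=chi2, p_value=p)


def curve_metrics(
    y_true: Sequence, score: Sequence[float], positive_class
) -> tuple[float, float]:
    """(ROC AUC, PR AUC) from continuous positive-class scores.

    ROC AUC is the rank statistic (ties counted one half, equivalent to the
    trapezoidal rule over thresholds); PR AUC uses step-wise interpolation
    (average precision). Raises on single-class truth, where ROC is
    undefined.
    """
    y_true = np.asarray(y_true)
    score = np.asarray(score, dtype=float)
    if y_true.shape != score.shape:
        raise ValueError("y_true and score must have equal length")
    y = (y_true == positive_class).astype(int)
    if y.min() == y.max():
        raise ValueError("ROC AUC is undefined for single-class truth")
    return float(roc_auc_score(y, score)), float(average_precision_score(y, score))
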