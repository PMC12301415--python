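"""Threshold metrics, ROC/PR curves, and decision-curve analysis.

The metric set mirrors the published comparison tables: precision (PRE),
sensitivity (SEN), specificity (SPE), accuracy (ACC), error rate (ER) and
F1, all on [0, 1], with PRE/F1 reported as absent when a classifier makes
no positive prediction (as a degenerate SVM does on an imbalanced cohort).
ROC-AUC uses the tie-grouped threshold sweep (equivalently the pairwise
probability P(score+ > score-) + 0.5 P(tie)); PR-AUC uses step-function
(average-precision) interpolation — trapezoidal PR interpolation is
deliberately avoided because it is optimistically biased.

Decision-curve analysis reports net benefit NB(p_t) = TP/n - FP/n *
p_t/(1-p_t) over a threshold-probability grid, against the treat-all and
treat-none reference strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

__all__ = [
    "MetricSet",
    "CurveSet",
    "NetBenefitCurve",
    "confusion_metrics",
    "roc_pr_curves",
    "decision_curve",
    "metric_table",
]


@dataclass(frozen=True)
class MetricSet:
    """Confusion-matrix metrics; undefined entries are NaN (printed as em-dash)."""

    PRE: float
    SEN: float
    SPE: float
    ACC: float
    ER: float
    F1: float

    def as_dict(self) -> dict:
        return {
            "PRE": self.PRE,
            "SEN": self.SEN,
            "SPE": self.SPE,
            "ACC": self.ACC,
            "ER": self.ER,
            "F1": self.F1,
        }


@dataclass
class CurveSet:
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    pr_thresholds: np.ndarray
    roc_auc: float
    pr_auc: float


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray
    nb_treat_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_treat_all": self.nb_treat_all,
                "nb_treat_none": self.nb_treat_none,
            }
        )


def _validate(labels, probabilities):
    labels = np.asarray(labels, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != probabilities.shape:
        raise ValueError("labels and probabilities must have equal length")
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if np.any((probabilities < 0) | (probabilities > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return labels, probabilities


def confusion_metrics(labels, probabilities, threshold: float = 0.5) -> MetricSet:
    """Threshold metrics; a prediction is positive iff probability >= threshold."""
    labels, probabilities = _validate(labels, probabilities)
    predictions = probabilities >= threshold
    tp = float(np.sum(predictions & (labels == 1)))
    fp = float(np.sum(predictions & (labels == 0)))
    fn = float(np.sum(~predictions & (labels == 1)))
    tn = float(np.sum(~predictions & (labels == 0)))
    n = tp + fp + fn + tn
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn > 0 else math.nan
    spe = tn / (tn + fp) if tn + fp > 0 else math.nan
    pre = tp / (tp + fp) if tp + fp > 0 else math.nan
    if math.isnan(pre) or math.isnan(sen) or pre + sen == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * pre * sen / (pre + sen)
    return MetricSet(PRE=pre, SEN=sen, SPE=spe, ACC=acc, ER=1.0 - acc, F1=f1)


def roc_pr_curves(labels, probabilities) -> CurveSet:
    """ROC and precision-recall curves with their areas."""
    labels, probabilities = _validate(labels, probabilities)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute ROC/PR curves")
    fpr, tpr, roc_thr = roc_curve(labels, probabilities)
    precision, recall, pr_thr = precision_recall_curve(labels, probabilities)
    return CurveSet(
        fpr=fpr,
        tpr=tpr,
        roc_thresholds=roc_thr,
        precision=precision,
        recall=recall,
        pr_thresholds=pr_thr,
        roc_auc=float(roc_auc_score(labels, probabilities)),
        pr_auc=float(average_precision_score(labels, probabilities)),
    )


def decision_curve(labels, probabilities, thresholds=None) -> NetBenefitCurve:
    """Net benefit of acting on the model at each threshold probability.

    Default grid: 99 points 0.01 ... 0.99.  p_t = 1 is excluded (the
    treat-all weight p_t/(1-p_t) diverges there).
    """
    labels, probabilities = _validate(labels, probabilities)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = labels.size
    n_pos = float(np.sum(labels == 1))
    n_neg = float(n - n_pos)
    weight = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, p_t in enumerate(thresholds):
        predictions = probabilities >= p_t
        tp = float(np.sum(predictions & (labels == 1)))
        fp = float(np.sum(predictions & (labels == 0)))
        nb_model[i] = tp / n - (fp / n) * weight[i]
    nb_all = n_pos / n - (n_neg / n) * weight
    return NetBenefitCurve(
        thresholds=thresholds,
        nb_model=nb_model,
        nb_treat_all=nb_all,
        nb_treat_none=np.zeros_like(thresholds),
    )


def metric_table(
    labels, model_probabilities: dict, threshold: float = 0.5
) -> pd.DataFrame:
    """Comparison table: one row per model, the published column layout.

    Columns PRE, SEN, SPE, ACC, F1, ROC-AUC, PR-AUC.  The error rate is
    available from :func:`confusion_metrics` but not shown, matching the
    published tables.
    """
    rows = []
    for name, probs in model_probabilities.items():
        metrics = confusion_metrics(labels, probs, threshold)
        curves = roc_pr_curves(labels, probs)
        rows.append(
            {
                "model": name,
                "PRE": metrics.PRE,
                "SEN": metrics.SEN,
                "SPE": metrics.SPE,
                "ACC": metrics.ACC,
                "F1": metrics.F1,
                "ROC-AUC": curves.roc_auc,
                "PR-AUC": curves.pr_auc,
            }
        )
    return pd.DataFrame(rows).set_index("model")
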