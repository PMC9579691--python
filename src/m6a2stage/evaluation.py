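"""Binary-classification and regression metrics.

Point metrics follow the standard contingency definitions:
Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total and
MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)), with MCC defined
as 0 when any denominator factor is zero.  Curves and areas (ROC/trapezoid
AUROC, PR/step-interpolated AUPRC) come from scikit-learn; the regression task
is scored by the Pearson correlation coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc, precision_recall_curve, roc_curve

from .encoding import MultiTaskBatch, encode_split
from .dataset_builder import DatasetSplit
from .networks import ModelState, predict

__all__ = [
    "ContingencyCounts",
    "EvalReport",
    "confusion",
    "point_metrics",
    "roc_pr_curves",
    "pearson",
    "evaluate_model",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ContingencyCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvalReport:
    """Seven-metric evaluation result with curve coordinates."""

    Sn: float
    Sp: float
    Acc: float
    MCC: float
    AUROC: float
    AUPRC: float
    pearson_r: float | None = None
    prob_vs_target_r: float | None = None  # classification prob vs regression target
    roc_curve: tuple[np.ndarray, np.ndarray] | None = None
    pr_curve: tuple[np.ndarray, np.ndarray] | None = None
    threshold: float = 0.5
    counts: ContingencyCounts | None = None

    def as_dict(self) -> dict:
        d = {
            "Sn": self.Sn, "Sp": self.Sp, "Acc": self.Acc, "MCC": self.MCC,
            "AUROC": self.AUROC, "AUPRC": self.AUPRC, "threshold": self.threshold,
        }
        if self.pearson_r is not None:
            d["pearson_r"] = self.pearson_r
        if self.prob_vs_target_r is not None:
            d["prob_vs_target_r"] = self.prob_vs_target_r
        return d


def confusion(labels: np.ndarray, probs: np.ndarray, threshold: float = 0.5) -> ContingencyCounts:
    """Hard-call contingency counts; a probability exactly at the threshold is
    called positive."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    if labels.shape != probs.shape:
        raise ValueError("labels and probs must have the same length")
    pred = probs >= threshold
    pos = labels == 1
    return ContingencyCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def point_metrics(c: ContingencyCounts) -> tuple[float, float, float, float]:
    """(Sn, Sp, Acc, MCC) from contingency counts.

    Undefined Sn or Sp (empty class) is reported as NaN with a warning; a zero
    factor in the MCC denominator yields MCC = 0.
    """
    if c.total == 0:
        raise ValueError("empty contingency table")
    TP, TN, FP, FN = c.TP, c.TN, c.FP, c.FN
    if TP + FN == 0:
        warnings.warn("no positive samples: Sn undefined (NaN)")
        sn = float("nan")
    else:
        sn = TP / (TP + FN)
    if TN + FP == 0:
        warnings.warn("no negative samples: Sp undefined (NaN)")
        sp = float("nan")
    else:
        sp = TN / (TN + FP)
    acc = (TP + TN) / c.total
    denom2 = (TP + FN) * (TN + FP) * (TP + FP) * (TN + FN)
    mcc = 0.0 if denom2 == 0 else (TP * TN - FN * FP) / np.sqrt(denom2)
    return sn, sp, acc, float(mcc)


def roc_pr_curves(labels: np.ndarray, probs: np.ndarray):
    """ROC and PR curves with areas.

    AUROC is the trapezoid area under the ROC threshold sweep (equivalently
    the normalized Mann-Whitney U statistic with ties counted one half);
    AUPRC uses step-wise interpolation, which avoids the optimistic bias of
    trapezoid interpolation in PR space.
    Returns ((fpr, tpr), auroc, (recall, precision), auprc).
    """
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least one positive and one negative label")
    fpr, tpr, _ = roc_curve(labels, probs)
    auroc = float(auc(fpr, tpr))
    precision, recall, _ = precision_recall_curve(labels, probs)
    # arrays run from high threshold to recall 0; step area = sum dR * P
    rec = recall[::-1]
    prec = precision[::-1]
    auprc = float(np.sum(np.diff(rec, prepend=0.0) * prec))
    return (fpr, tpr), auroc, (rec, prec), auprc


def pearson(X: np.ndarray, Y: np.ndarray) -> float:
    """Pearson product-moment correlation; zero variance is an error, not 0."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.size < 2:
        raise ValueError("X and Y must have equal length >= 2")
    if np.var(X) == 0 or np.var(Y) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    return float(stats.pearsonr(X, Y).statistic)


def evaluate_predictions(
    labels: np.ndarray,
    probs: np.ndarray,
    threshold: float = 0.5,
    regression_preds: np.ndarray | None = None,
    regression_targets: np.ndarray | None = None,
) -> EvalReport:
    c = confusion(labels, probs, threshold)
    sn, sp, acc, mcc = point_metrics(c)
    roc, auroc, pr, auprc = roc_pr_curves(labels, probs)
    r = rp = None
    if regression_preds is not None and regression_targets is not None:
        r = pearson(regression_preds, regression_targets)
        rp = pearson(probs, regression_targets)
    return EvalReport(
        Sn=sn, Sp=sp, Acc=acc, MCC=mcc, AUROC=auroc, AUPRC=auprc,
        pearson_r=r, prob_vs_target_r=rp, roc_curve=roc, pr_curve=pr,
        threshold=threshold, counts=c,
    )


def evaluate_model(
    state: ModelState,
    split: DatasetSplit | MultiTaskBatch,
    threshold: float = 0.5,
) -> EvalReport:
    """Full evaluation of a trained model on a split.

    In multitask mode the report additionally carries the Pearson r of the
    regression head against the targets and, for comparison, the Pearson r of
    the positive-class probability against the same targets (the latter is the
    "use the classifier's probability as confidence" baseline).
    """
    batch = encode_split(split) if isinstance(split, DatasetSplit) else split
    predict(state, batch)
    labels = batch.class_labels[:, 1].astype(int)
    probs = batch.class_probs[:, 1]
    reg_preds = batch.regression_preds if state.mode == "multitask" else None
    reg_targets = batch.regression_targets if state.mode == "multitask" else None
    return evaluate_predictions(
        labels, probs, threshold=threshold,
        regression_preds=reg_preds, regression_targets=reg_targets,
    )
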