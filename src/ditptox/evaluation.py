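"""Binary-classification metrics: SE, SP, ACC, MCC and rank-based AUC.

From the 2x2 confusion matrix (positive class = 1):

    ACC = (TP + TN) / (TP + FP + TN + FN)
    SE  = TP / (TP + FN)                      (sensitivity, toxicant recall)
    SP  = TN / (TN + FP)                      (specificity)
    MCC = (TP*TN - FP*FN) / sqrt((FP+TN)(FP+TP)(FN+TN)(FN+TP))

AUC uses the Mann-Whitney formulation: the fraction of (positive,
negative) score pairs ranked correctly, ties counted one half — computed
from tie-averaged ranks, hence invariant to strictly monotone transforms
of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "EvaluationError",
    "confusion_from_predictions",
    "classification_metrics",
    "auc_score",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.total == 0:
            raise EvaluationError("confusion matrix must have at least one entry")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    """SE/SP/ACC in [0,1], MCC in [-1,1], AUC in [0,1] (None when scores
    were unavailable). Degenerate denominators are flagged, not raised."""

    SE: float
    SP: float
    ACC: float
    MCC: float
    AUC: float | None = None
    se_undefined: bool = False
    sp_undefined: bool = False
    mcc_degenerate: bool = False

    def rounded(self) -> dict:
        """Report formatting: percentages to 1 d.p., MCC/AUC to 3 d.p."""
        return {
            "SE_pct": round(100 * self.SE, 1),
            "SP_pct": round(100 * self.SP, 1),
            "ACC_pct": round(100 * self.ACC, 1),
            "MCC": round(self.MCC, 3),
            "AUC": None if self.AUC is None else round(self.AUC, 3),
        }


def _check_binary(a: np.ndarray, what: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise EvaluationError(f"{what} must contain only 0/1 values")
    return a.astype(int)


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    """Standard 2x2 cross-tabulation with positive class 1."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if len(y_true) != len(y_pred):
        raise EvaluationError(
            f"length mismatch: {len(y_true)} labels vs {len(y_pred)} predictions"
        )
    return ConfusionMatrix(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def classification_metrics(cm: ConfusionMatrix) -> MetricSet:
    """SE, SP, ACC and MCC from a confusion matrix.

    A zero MCC denominator factor returns MCC = 0 with the degenerate flag
    set; an empty positive (or negative) margin flags SE (or SP) undefined
    and reports 0 for it.
    """
    tp, fp, tn, fn = cm.TP, cm.FP, cm.TN, cm.FN
    se_undefined = (tp + fn) == 0
    sp_undefined = (tn + fp) == 0
    se = 0.0 if se_undefined else tp / (tp + fn)
    sp = 0.0 if sp_undefined else tn / (tn + fp)
    acc = (tp + tn) / cm.total
    denom = (fp + tn) * (fp + tp) * (fn + tn) * (fn + tp)
    mcc_degenerate = denom == 0
    mcc = 0.0 if mcc_degenerate else (tp * tn - fp * fn) / np.sqrt(denom)
    return MetricSet(
        SE=se, SP=sp, ACC=acc, MCC=float(mcc),
        se_undefined=se_undefined, sp_undefined=sp_undefined,
        mcc_degenerate=mcc_degenerate,
    )


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve, Mann-Whitney form.

    Equals the probability that a random positive outranks a random
    negative, with tied scores counted 1/2.
    """
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    if len(y_true) != len(scores):
        raise EvaluationError("labels and scores must have equal length")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum_pos = ranks[y_true == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
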