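"""Diagnostic accuracy and model-comparison statistics.

Everything operates on pooled out-of-fold predictions: 3x3 confusion
matrices in the fixed class order (adipose, fibroglandular, tumor),
one-vs-rest sensitivity/specificity, pooled-score ROC/AUC, cross-model
transition tables over the tumor-actual pixels, net-gain summaries, and
paired symmetry tests (Bowker's k x k test and the binary McNemar test
with continuity correction).

Percentages are rounded half-up to one decimal when displayed, matching
the convention of printed diagnostic tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.metrics import roc_curve

from .core import CLASSES

__all__ = ["ConfusionMatrix3", "ClassMetrics", "TransitionTable",
           "SymmetryTestResult", "confusion_matrix", "sensitivity",
           "specificity", "roc_auc", "transition_table", "net_gain",
           "bowker_test", "mcnemar_binary_cc", "metrics_table",
           "percent_round"]


def percent_round(fraction: float, decimals: int = 1) -> float:
    """Fraction -> percent, rounded half-up (printed-table convention)."""
    scale = 10 ** decimals
    return float(np.floor(fraction * 100.0 * scale + 0.5) / scale)


@dataclass(frozen=True)
class ConfusionMatrix3:
    """counts[actual, predicted] over the fixed class order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_total(self, cls: str) -> int:
        return int(self.counts[CLASSES.index(cls)].sum())

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASSES),
                            columns=list(CLASSES))


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float
    specificity: float
    auc: float | None = None


@dataclass(frozen=True)
class TransitionTable:
    """counts[prediction under model A, prediction under model B] over a
    fixed pixel subset (by default the tumor-actual pixels)."""

    counts: np.ndarray
    subset: str = "actual == tumor"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or np.any(c < 0):
            raise ValueError("transition table must be 3x3 non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASSES),
                            columns=list(CLASSES))


@dataclass(frozen=True)
class SymmetryTestResult:
    statistic: float
    df: int
    p_value: float
    variant: str              # "bowker" or "mcnemar_binary_cc"
    defined: bool = True


def confusion_matrix(preds: pd.DataFrame) -> ConfusionMatrix3:
    """3x3 confusion matrix from pooled predictions."""
    for col in ("true_label", "pred_label"):
        bad = ~preds[col].isin(CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown class in {col}: "
                f"{sorted(preds.loc[bad, col].unique())}")
    counts = np.zeros((3, 3), dtype=int)
    ai = preds["true_label"].map({c: i for i, c in enumerate(CLASSES)})
    pi = preds["pred_label"].map({c: i for i, c in enumerate(CLASSES)})
    np.add.at(counts, (ai.to_numpy(), pi.to_numpy()), 1)
    return ConfusionMatrix3(counts=counts)


def sensitivity(cm: ConfusionMatrix3, cls: str) -> float:
    """Per-class sensitivity: correct / all actual-cls records."""
    i = CLASSES.index(cls)
    row = cm.counts[i].sum()
    if row == 0:
        raise ValueError(f"no actual {cls} records; sensitivity undefined")
    return float(cm.counts[i, i] / row)


def specificity(cm: ConfusionMatrix3, cls: str) -> float:
    """One-vs-rest specificity: non-cls records not predicted as cls."""
    i = CLASSES.index(cls)
    mask = np.arange(3) != i
    negatives = cm.counts[mask].sum()
    if negatives == 0:
        raise ValueError(f"no non-{cls} records; specificity undefined")
    false_pos = cm.counts[mask, i].sum()
    return float((negatives - false_pos) / negatives)


def roc_auc(preds: pd.DataFrame, cls: str
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest pooled ROC for a class; AUC by the trapezoid rule.

    Ties in the score are grouped at a common threshold, so the AUC equals
    P(score_pos > score_neg) + 0.5 P(tie).  Returns (fpr, tpr, auc);
    constant scores give AUC 0.5 with a warning.
    """
    y = (preds["true_label"] == cls).to_numpy(int)
    s = preds[f"score_{cls}"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError(f"need both positive and negative records for {cls}")
    if np.all(s == s[0]):
        warnings.warn(f"constant scores for {cls}; AUC set to 0.5")
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def transition_table(preds_a: pd.DataFrame, preds_b: pd.DataFrame,
                     actual_class: str = "tumor") -> TransitionTable:
    """Cross-model 3x3 classification-change counts over one actual class.

    The two prediction sets must describe the same records in the same
    order (same patients and true labels)."""
    if len(preds_a) != len(preds_b):
        raise ValueError("prediction sets differ in length")
    same = (preds_a["patient_id"].to_numpy() == preds_b["patient_id"].to_numpy()) \
        & (preds_a["true_label"].to_numpy() == preds_b["true_label"].to_numpy())
    if not same.all():
        raise ValueError("prediction sets describe different records")
    mask = preds_a["true_label"] == actual_class
    counts = np.zeros((3, 3), dtype=int)
    ia = preds_a.loc[mask, "pred_label"].map(
        {c: i for i, c in enumerate(CLASSES)})
    ib = preds_b.loc[mask, "pred_label"].map(
        {c: i for i, c in enumerate(CLASSES)})
    np.add.at(counts, (ia.to_numpy(), ib.to_numpy()), 1)
    return TransitionTable(counts=counts,
                           subset=f"actual == {actual_class}")


def net_gain(tt: TransitionTable, target: str = "tumor"
             ) -> dict[str, float]:
    """Correct-classification gain moving from model A to model B.

    gained: records predicted ``target`` by B but not by A; lost: the
    reverse; pct: net gain as a share of the subset (percent)."""
    t = CLASSES.index(target)
    other = [i for i in range(3) if i != t]
    gained = int(tt.counts[other, t].sum())
    lost = int(tt.counts[t, other].sum())
    net = gained - lost
    return {"gained": gained, "lost": lost, "net": net,
            "pct": percent_round(net / tt.total)}


def bowker_test(tt: TransitionTable) -> SymmetryTestResult:
    """Bowker's chi-square test of symmetry for the 3x3 paired table.

    chi2 = sum over off-diagonal pairs with n_ij + n_ji > 0 of
    (n_ij - n_ji)^2 / (n_ij + n_ji); df = number of included pairs.
    All-zero off-diagonal pairs leave the statistic undefined
    (``defined=False``)."""
    c = tt.counts
    stat, dof = 0.0, 0
    for i in range(3):
        for j in range(i + 1, 3):
            denom = c[i, j] + c[j, i]
            if denom > 0:
                stat += (c[i, j] - c[j, i]) ** 2 / denom
                dof += 1
    if dof == 0:
        return SymmetryTestResult(statistic=float("nan"), df=0,
                                  p_value=float("nan"), variant="bowker",
                                  defined=False)
    return SymmetryTestResult(statistic=float(stat), df=dof,
                              p_value=float(chi2.sf(stat, dof)),
                              variant="bowker")


def mcnemar_binary_cc(tt: TransitionTable, target: str = "tumor"
                      ) -> SymmetryTestResult:
    """Binary McNemar test with continuity correction.

    The table is collapsed to correct/incorrect with respect to ``target``;
    b = incorrect under A but correct under B, c = the reverse;
    chi2 = (|b - c| - 1)^2 / (b + c) on 1 df."""
    t = CLASSES.index(target)
    other = [i for i in range(3) if i != t]
    b = int(tt.counts[other, t].sum())
    c = int(tt.counts[t, other].sum())
    if b + c == 0:
        return SymmetryTestResult(statistic=float("nan"), df=1,
                                  p_value=float("nan"),
                                  variant="mcnemar_binary_cc", defined=False)
    stat = (abs(b - c) - 1) ** 2 / (b + c)
    return SymmetryTestResult(statistic=float(stat), df=1,
                              p_value=float(chi2.sf(stat, 1)),
                              variant="mcnemar_binary_cc")


def metrics_table(preds: pd.DataFrame | None = None,
                  cm: ConfusionMatrix3 | None = None
                  ) -> dict[str, ClassMetrics]:
    """Per-class sensitivity/specificity (and AUC when scores are given)."""
    if cm is None:
        if preds is None:
            raise ValueError("need predictions or a confusion matrix")
        cm = confusion_matrix(preds)
    out = {}
    for cls in CLASSES:
        auc = None
        if preds is not None and f"score_{cls}" in preds.columns:
            _, _, auc = roc_auc(preds, cls)
        out[cls] = ClassMetrics(sensitivity=sensitivity(cm, cls),
                                specificity=specificity(cm, cls), auc=auc)
    return out
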