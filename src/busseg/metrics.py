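"""Overlap and confusion-matrix evaluation battery.

The report row carries, in order: Loss, Acc, DC, Sen, Sp, F1, Pc, M-IOU,
AUC (pixel-pooled ROC), with PR-AUC reported alongside.  Lesion pixels are
the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc, precision_recall_curve, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "REPORT_COLUMNS",
    "dice_coefficient",
    "dice_loss",
    "confusion",
    "scalar_metrics",
    "iou",
    "mean_iou",
    "auc_curves",
    "evaluate_masks",
]

#: column order of the aggregate report row
REPORT_COLUMNS = ("Loss", "Acc", "DC", "Sen", "Sp", "F1", "Pc", "M-IOU", "AUC")

DEFAULT_SMOOTH = 1.0


def _check_binary(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:10]}")
    return m.astype(np.float64)


def _check_shapes(x, y):
    if np.shape(x) != np.shape(y):
        raise ValueError(f"shape mismatch: {np.shape(x)} vs {np.shape(y)}")


def dice_coefficient(x: np.ndarray, y: np.ndarray,
                     smooth: float = DEFAULT_SMOOTH) -> float:
    """2|X∩Y| / (|X|+|Y|), smoothed so the empty-empty case is 1.

    ``y`` may be a soft probability map (soft Dice); ``x`` must be binary.
    """
    _check_shapes(x, y)
    x = _check_binary(x, "gold mask")
    y = np.asarray(y, dtype=np.float64)
    inter = float((x * y).sum())
    return (2.0 * inter + smooth) / (float(x.sum() + y.sum()) + smooth)


def dice_loss(x: np.ndarray, y: np.ndarray,
              smooth: float = DEFAULT_SMOOTH) -> float:
    """1 - Dice coefficient."""
    return 1.0 - dice_coefficient(x, y, smooth=smooth)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(gold: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts; lesion (1) is the positive class."""
    _check_shapes(gold, pred)
    g = _check_binary(gold, "gold mask").astype(bool)
    p = _check_binary(pred, "predicted mask").astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(g & p)),
        fp=int(np.sum(~g & p)),
        fn=int(np.sum(g & ~p)),
        tn=int(np.sum(~g & ~p)),
    )


def _ratio(num: float, den: float) -> float:
    """Table-2 ratio with the zero-denominator -> 0 convention."""
    return num / den if den > 0 else 0.0


def scalar_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, sensitivity, specificity and F1 from counts."""
    acc = _ratio(c.tp + c.tn, c.total)
    pc = _ratio(c.tp, c.tp + c.fp)
    sen = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    f1 = _ratio(2.0 * pc * sen, pc + sen)
    return {"acc": acc, "pc": pc, "sen": sen, "sp": sp, "f1": f1}


def iou(x: np.ndarray, y: np.ndarray) -> float:
    """Lesion-class intersection over union; empty-empty counts as 1."""
    _check_shapes(x, y)
    xb = _check_binary(x, "gold mask").astype(bool)
    yb = _check_binary(y, "predicted mask").astype(bool)
    union = int(np.sum(xb | yb))
    if union == 0:
        return 1.0
    return int(np.sum(xb & yb)) / union


def mean_iou(pairs) -> float:
    """Mean over (gold, predicted) mask pairs of the lesion-class IOU."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("mean_iou requires at least one mask pair")
    return float(np.mean([iou(x, y) for x, y in pairs]))


def auc_curves(gold, prob):
    """Pixel-pooled ROC-AUC and precision-recall AUC.

    ``gold``: binary masks; ``prob``: matching probability maps in [0, 1].
    Raises if the pooled gold pixels are single-class (AUC undefined).
    """
    gold = [np.asarray(g) for g in gold]
    prob = [np.asarray(p) for p in prob]
    for g, p in zip(gold, prob):
        _check_shapes(g, p)
    y = np.concatenate([_check_binary(g, "gold mask").ravel() for g in gold])
    s = np.concatenate([p.ravel() for p in prob]).astype(np.float64)
    if s.min() < 0 or s.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if y.min() == y.max():
        raise ValueError("AUC undefined: pooled gold pixels are single-class")
    roc = float(roc_auc_score(y, s))
    prec, rec, _ = precision_recall_curve(y, s)
    pr = float(auc(rec, prec))
    return roc, pr


@dataclass
class MetricsReport:
    """One evaluation row: the nine headline scores plus PR-AUC."""

    loss: float
    acc: float
    dc: float
    sen: float
    sp: float
    f1: float
    pc: float
    m_iou: float
    auc_roc: float
    auc_pr: float

    def to_row(self) -> dict:
        return {
            "Loss": self.loss, "Acc": self.acc, "DC": self.dc,
            "Sen": self.sen, "Sp": self.sp, "F1": self.f1, "Pc": self.pc,
            "M-IOU": self.m_iou, "AUC": self.auc_roc, "AUC-PR": self.auc_pr,
        }


def evaluate_masks(gold, prob, threshold: float = 0.5,
                   smooth: float = DEFAULT_SMOOTH) -> MetricsReport:
    """Full battery over a test set of gold masks and probability maps.

    DC and Loss are the soft Dice of the pooled probabilities (so
    loss + DC = 1 exactly); Acc/Sen/Sp/F1/Pc come from pooled confusion
    counts after binarizing at ``threshold``; M-IOU averages the per-image
    lesion IOU of the binarized masks.
    """
    gold = [np.asarray(g) for g in gold]
    prob = [np.asarray(p, dtype=np.float64) for p in prob]
    if not gold or len(gold) != len(prob):
        raise ValueError("need equal, non-empty gold and probability lists")
    g_all = np.concatenate([g.ravel() for g in gold])
    p_all = np.concatenate([p.ravel() for p in prob])
    dc = dice_coefficient(g_all, p_all, smooth=smooth)
    pred = [(p >= threshold).astype(np.uint8) for p in prob]
    counts = confusion(g_all, np.concatenate([p.ravel() for p in pred]))
    scal = scalar_metrics(counts)
    miou = mean_iou(list(zip(gold, pred)))
    roc, pr = auc_curves(gold, prob)
    return MetricsReport(
        loss=1.0 - dc, acc=scal["acc"], dc=dc, sen=scal["sen"],
        sp=scal["sp"], f1=scal["f1"], pc=scal["pc"], m_iou=miou,
        auc_roc=roc, auc_pr=pr)
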