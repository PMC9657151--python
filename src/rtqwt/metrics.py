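"""Binary-classification performance panel.

Confusion counts plus the standard panel — accuracy (ACC), sensitivity
(SEN), specificity (SPE), F1 and the Matthews correlation coefficient
(MCC) — and rank-based ROC/AUC.  Degenerate 0/0 cells are defined as 0
with a warning rather than raising mid-pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import InvalidInputError

__all__ = ["ConfusionCounts", "confusion", "metric_panel", "roc_auc"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: object = 1

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Standard 2x2 counts with an explicit positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("y_true and y_pred must have equal length")
    seen = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(seen) > 2:
        raise InvalidInputError(f"more than two labels present: {sorted(map(str, seen))}")
    if positive_class not in seen:
        raise InvalidInputError(f"positive class {positive_class!r} absent from labels")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        positive_class=positive_class,
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s is 0/0: defined as 0", name)
        return 0.0
    return num / den


def metric_panel(c: ConfusionCounts) -> dict[str, float]:
    """ACC, SEN, SPE, F1 and MCC from pooled confusion counts (fractions in [0, 1])."""
    if c.total == 0:
        raise InvalidInputError("empty confusion counts")
    tp, fp, tn, fn = (float(v) for v in (c.tp, c.fp, c.tn, c.fn))
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "ACC": (tp + tn) / c.total,
        "SEN": _safe_div(tp, tp + fn, "SEN"),
        "SPE": _safe_div(tn, tn + fp, "SPE"),
        "F1": _safe_div(2 * tp, 2 * tp + fp + fn, "F1"),
        "MCC": _safe_div(tp * tn - fp * fn, float(mcc_den), "MCC"),
    }


def roc_auc(decision_values, y_true) -> tuple[float, np.ndarray]:
    """AUC by the rank (Mann-Whitney) formulation plus swept ROC points.

    ``y_true`` is boolean/binary with True marking the positive class.
    Ties in the scores receive midranks, so identical scores for both
    classes give AUC = 0.5.  Returns (auc, points) where points is an
    (n_thresholds, 2) array of (FPR, TPR) pairs from a threshold sweep.
    """
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray(y_true).astype(bool)
    if scores.shape != y.shape:
        raise InvalidInputError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise InvalidInputError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("both classes must be present for ROC analysis")

    ranks = rankdata(scores)  # midranks for ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    points = np.empty((thresholds.size, 2))
    for i, thr in enumerate(thresholds):
        pred = scores >= thr
        points[i] = (np.sum(pred & ~y) / n_neg, np.sum(pred & y) / n_pos)
    return float(auc), points
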