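"""Single-marker ROC curves, AUC and sensitivity-constrained cutoffs.

Cutoffs are placed at midpoints between adjacent distinct scores (plus the
two trivial endpoints); the classification rule at cutoff ``c`` with
direction ``higher`` predicts infected when ``score > c``.  AUC is the
trapezoidal area, identical to the tie-corrected concordance probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RocPoint", "RocCurve", "CutoffChoice", "roc_curve", "auc", "cutoff_at_min_sensitivity"]


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocCurve:
    marker: str
    direction: str  # "higher" (higher score => infected) or "lower"
    points: tuple[RocPoint, ...]
    auc: float


@dataclass(frozen=True)
class CutoffChoice:
    cutoff: float
    sensitivity: float
    specificity: float
    low_information: bool = False  # SE constraint only met at SP == 0


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == "higher":
        return scores
    if direction == "lower":
        return -scores
    raise ValueError(f"unknown direction {direction!r}")


def roc_curve(scores, labels, direction: str = "higher", marker: str = "") -> RocCurve:
    """Build the empirical ROC curve of ``scores`` against boolean ``labels``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve: both classes must be present")

    s = _oriented(scores, direction)
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cutoffs = np.concatenate([[-np.inf], mids, [np.inf]])

    points = []
    for c in cutoffs:
        pred = s > c
        tp = int((pred & labels).sum())
        tn = int((~pred & ~labels).sum())
        points.append(
            RocPoint(
                cutoff=float(c if direction == "higher" else -c),
                sensitivity=tp / n_pos,
                specificity=tn / n_neg,
            )
        )

    # trapezoid over (FPR, TPR); ties in FPR ordered by TPR so the path is
    # the monotone ROC staircase
    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    order = np.lexsort((tpr, fpr))
    area = float(np.trapezoid(tpr[order], fpr[order]))
    return RocCurve(marker=marker, direction=direction, points=tuple(points), auc=area)


def auc(roc: RocCurve) -> float:
    return roc.auc


def cutoff_at_min_sensitivity(roc: RocCurve, se_min: float) -> CutoffChoice:
    """Most specific attainable ROC point with sensitivity >= ``se_min``.

    Ties in specificity are broken toward higher sensitivity, then toward
    the cutoff excluding more non-infected patients.  When the constraint
    is only attainable at zero specificity the returned choice carries
    ``low_information=True`` (the table prints "-" for such cutoffs).
    """
    if not (0.0 < se_min <= 1.0):
        raise ValueError("se_min must lie in (0, 1]")
    feasible = [p for p in roc.points if p.sensitivity >= se_min]
    if not feasible:
        raise ValueError(f"no ROC point reaches sensitivity {se_min}")
    sign = 1.0 if roc.direction == "higher" else -1.0
    best = max(feasible, key=lambda p: (p.specificity, p.sensitivity, sign * p.cutoff))
    return CutoffChoice(
        cutoff=best.cutoff,
        sensitivity=best.sensitivity,
        specificity=best.specificity,
        low_information=best.specificity == 0.0,
    )
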