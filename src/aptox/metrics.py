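"""Performance measures for binary toxicity prediction models.

Confusion-matrix metrics (Se, Sp, balanced accuracy, PPV, NPV, F1, Youden
index), Mann–Whitney ROC AUC, decision-curve net benefit, precision–recall
and calibration curves. Percentages are printed half-up to one decimal,
matching clinical reporting; the printed balanced accuracy is the mean of
the *rounded* Se and Sp, the convention under which published tables of
this kind are internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionSummary",
    "DecisionCurve",
    "confusion_metrics",
    "confusion_from_predictions",
    "roc_auc",
    "decision_curve",
    "precision_recall_curve",
    "calibration_curve",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and every derived rate, on the fraction scale.

    ``ppv``/``npv`` are None when their denominator is zero (flagged
    undefined rather than silently 0).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be >= 0")
        if self.tp + self.fn < 1 or self.tn + self.fp < 1:
            raise ValueError("each outcome class needs at least one member")

    @property
    def se(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def bacc(self) -> float:
        return (self.se + self.sp) / 2.0

    @property
    def youden(self) -> float:
        return self.se + self.sp - 1.0

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return None if d == 0 else self.tp / d

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return None if d == 0 else self.tn / d

    @property
    def f1(self) -> float:
        return 2 * self.tp / (2 * self.tp + self.fp + self.fn)

    def printed(self) -> dict[str, float | None]:
        """Percent-scale values as a clinical table prints them.

        Se/Sp/PPV/NPV are rounded half-up to one decimal; Bacc is the mean
        of the rounded Se and Sp, re-rounded; F1 is on the 0–1 scale at two
        decimals.
        """
        se = round_half_up(100 * self.se)
        sp = round_half_up(100 * self.sp)
        return {
            "se": se,
            "sp": sp,
            "bacc": round_half_up((se + sp) / 2.0),
            "ppv": None if self.ppv is None else round_half_up(100 * self.ppv),
            "npv": None if self.npv is None else round_half_up(100 * self.npv),
            "f1": round_half_up(self.f1, 2),
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionSummary:
    """Summary of a 2x2 confusion table (positive = toxicity event)."""
    return ConfusionSummary(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))


def confusion_from_predictions(y_true, y_pred) -> ConfusionSummary:
    y = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    return confusion_metrics(
        tp=int(((p == 1) & (y == 1)).sum()),
        fp=int(((p == 1) & (y == 0)).sum()),
        tn=int(((p == 0) & (y == 0)).sum()),
        fn=int(((p == 0) & (y == 1)).sum()),
    )


def roc_auc(probabilities, labels) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(p)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class DecisionCurve:
    """Net benefit of the model vs treat-all vs treat-none per threshold."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray


def decision_curve(probabilities, labels, thresholds=None) -> DecisionCurve:
    """Decision-curve analysis.

    nb_model(p) = TP/n - FP/n * p/(1-p), classifying positive when the
    predicted probability exceeds p; nb_all assumes everyone is treated;
    nb_none is identically 0. Thresholds must lie in [0, 1).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.0, 1.0, 0.01)
    t = np.asarray(thresholds, dtype=float)
    if np.any((t < 0) | (t >= 1)):
        raise ValueError("thresholds must lie in [0, 1)")
    n = y.size
    prevalence = y.mean()
    odds = t / (1.0 - t)
    pred = p[None, :] > t[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    nb_model = tp / n - fp / n * odds
    nb_all = prevalence - (1 - prevalence) * odds
    return DecisionCurve(
        thresholds=t,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=np.zeros_like(t),
    )


def precision_recall_curve(probabilities, labels) -> np.ndarray:
    """(threshold, precision, recall) at every distinct probability cut.

    The classification rule is positive when p >= threshold, so the curve
    starts at full recall and ends at the highest score.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    n_pos = (y == 1).sum()
    rows = []
    for t in np.unique(p):
        pred = p >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        precision = tp / (tp + fp) if tp + fp else 1.0
        rows.append((t, precision, tp / n_pos))
    return np.asarray(rows)


def calibration_curve(probabilities, labels, bins: int = 10) -> np.ndarray:
    """(bin centre, mean predicted, observed rate, count) per equal-width bin.

    Empty bins are omitted.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append((
            (edges[b] + edges[b + 1]) / 2.0,
            float(p[sel].mean()),
            float(y[sel].mean()),
            int(sel.sum()),
        ))
    return np.asarray(rows)
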