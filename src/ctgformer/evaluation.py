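"""ROC analysis, operating-point selection and the clinical metric panel.

The decision rule is everywhere "positive iff score >= threshold".  The
empirical ROC enumerates the distinct scores (plus a sentinel above the
maximum), AUC is the trapezoidal area over FPR — equal, including ties, to
the Mann-Whitney pairwise-ordering probability — and four operating points
are supported: the default 0.5 threshold, the Youden-index maximiser
(ties broken toward the higher threshold, i.e. higher specificity), and
floors on sensitivity or specificity.  Zero-denominator metrics are
reported as NaN, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AUCUndefinedError, ParameterError, UnreachableTargetError

__all__ = [
    "PredictionSet",
    "MetricReport",
    "OperatingPoint",
    "roc_curve",
    "auc",
    "auc_mann_whitney",
    "youden_threshold",
    "threshold_at_sensitivity",
    "threshold_at_specificity",
    "default_threshold",
    "metrics_at",
    "operating_points",
    "temporal_sweep",
]


@dataclass
class PredictionSet:
    """Per-window scores and labels, optionally with ids and days to delivery."""

    scores: np.ndarray
    labels: np.ndarray
    ids: np.ndarray | None = None
    days_to_delivery: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ParameterError("scores and labels must have equal length")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ParameterError("scores must be probabilities in [0, 1]")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ParameterError("labels must be binary")

    def both_classes(self) -> bool:
        return 0 < self.labels.sum() < len(self.labels)


@dataclass
class MetricReport:
    """Confusion counts and the six derived clinical metrics.

    Undefined ratios (zero denominator) are NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    f1: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self):
        def ratio(num, den):
            return num / den if den > 0 else float("nan")

        self.sensitivity = ratio(self.tp, self.tp + self.fn)
        self.specificity = ratio(self.tn, self.tn + self.fp)
        self.ppv = ratio(self.tp, self.tp + self.fp)
        self.npv = ratio(self.tn, self.tn + self.fn)
        denom = 2 * self.tp + self.fp + self.fn
        self.f1 = ratio(2 * self.tp, denom)
        self.accuracy = ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "f1": self.f1,
            "accuracy": self.accuracy,
        }


@dataclass
class OperatingPoint:
    """A chosen threshold with its metric panel."""

    threshold: float
    kind: str
    metrics: MetricReport


def roc_curve(pred: PredictionSet) -> pd.DataFrame:
    """Empirical ROC as a DataFrame of (threshold, tpr, fpr).

    Thresholds are the distinct scores in descending order, preceded by a
    sentinel above the maximum (the all-negative corner).  With the
    ``score >= threshold`` rule the curve runs from (0, 0) to (1, 1) with
    monotone TPR and FPR.
    """
    if not pred.both_classes():
        raise AUCUndefinedError("ROC requires both classes")
    n_pos = int(pred.labels.sum())
    n_neg = len(pred.labels) - n_pos
    distinct = np.unique(pred.scores)[::-1]
    thresholds = np.concatenate([[np.inf], distinct])
    rows = []
    for t in thresholds:
        positive = pred.scores >= t
        tp = int(np.sum(positive & (pred.labels == 1)))
        fp = int(np.sum(positive & (pred.labels == 0)))
        rows.append({"threshold": t, "tpr": tp / n_pos, "fpr": fp / n_neg})
    return pd.DataFrame(rows)


def auc(roc: pd.DataFrame) -> float:
    """Trapezoidal area under the ROC over FPR."""
    return float(np.trapezoid(roc["tpr"], roc["fpr"]))


def auc_mann_whitney(pred: PredictionSet) -> float:
    """Tie-corrected pairwise-ordering probability (rank-statistic AUC)."""
    if not pred.both_classes():
        raise AUCUndefinedError("AUC requires both classes")
    from scipy.stats import rankdata

    pos = pred.scores[pred.labels == 1]
    neg = pred.scores[pred.labels == 0]
    ranks = rankdata(np.concatenate([pos, neg]))
    return float(
        (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0)
        / (len(pos) * len(neg))
    )


def metrics_at(pred: PredictionSet, threshold: float) -> MetricReport:
    """Confusion counts and metrics at one threshold (positive iff >=)."""
    positive = pred.scores >= threshold
    tp = int(np.sum(positive & (pred.labels == 1)))
    fp = int(np.sum(positive & (pred.labels == 0)))
    fn = int(np.sum(~positive & (pred.labels == 1)))
    tn = int(np.sum(~positive & (pred.labels == 0)))
    return MetricReport(tp=tp, fp=fp, tn=tn, fn=fn)


def default_threshold(pred: PredictionSet, threshold: float = 0.5) -> OperatingPoint:
    """The fixed default decision threshold (0.5)."""
    return OperatingPoint(threshold, "default", metrics_at(pred, threshold))


def youden_threshold(pred: PredictionSet) -> OperatingPoint:
    """Threshold maximising J = sensitivity + specificity - 1.

    Candidates are the distinct scores; ties in J are broken toward the
    HIGHER threshold (fewer false alarms).
    """
    if not pred.both_classes():
        raise AUCUndefinedError("Youden index requires both classes")
    best_t, best_j = None, -np.inf
    for t in np.unique(pred.scores)[::-1]:  # descending: first win keeps high t
        m = metrics_at(pred, t)
        j = m.sensitivity + m.specificity - 1.0
        if j > best_j:
            best_t, best_j = t, j
    return OperatingPoint(float(best_t), "youden", metrics_at(pred, best_t))


def threshold_at_sensitivity(pred: PredictionSet, target: float) -> OperatingPoint:
    """Highest threshold whose sensitivity >= target.

    Maximises specificity subject to the sensitivity floor; raises when no
    threshold reaches the target.
    """
    if not (0.0 < target <= 1.0):
        raise ParameterError("target must be in (0, 1]")
    if not pred.both_classes():
        raise AUCUndefinedError("operating point requires both classes")
    for t in np.unique(pred.scores)[::-1]:
        m = metrics_at(pred, t)
        if m.sensitivity >= target:
            return OperatingPoint(float(t), "high_sensitivity", m)
    raise UnreachableTargetError(f"no threshold reaches sensitivity {target}")


def threshold_at_specificity(pred: PredictionSet, target: float) -> OperatingPoint:
    """Lowest threshold whose specificity >= target (maximises sensitivity)."""
    if not (0.0 < target <= 1.0):
        raise ParameterError("target must be in (0, 1]")
    if not pred.both_classes():
        raise AUCUndefinedError("operating point requires both classes")
    for t in np.unique(pred.scores):  # ascending: first win keeps low t
        m = metrics_at(pred, t)
        if m.specificity >= target:
            return OperatingPoint(float(t), "high_specificity", m)
    raise UnreachableTargetError(f"no threshold reaches specificity {target}")


def operating_points(
    pred: PredictionSet,
    sensitivity_target: float = 0.90,
    specificity_target: float = 0.90,
) -> dict[str, OperatingPoint]:
    """The four standard operating points for one prediction set."""
    out = {
        "default": default_threshold(pred),
        "youden": youden_threshold(pred),
    }
    try:
        out["high_sensitivity"] = threshold_at_sensitivity(pred, sensitivity_target)
    except UnreachableTargetError:
        pass
    try:
        out["high_specificity"] = threshold_at_specificity(pred, specificity_target)
    except UnreachableTargetError:
        pass
    return out


def temporal_sweep(pred: PredictionSet, day_thresholds=range(1, 8)) -> pd.DataFrame:
    """Evaluate AUC on nested days-to-delivery subsets of the cases.

    For each bound ``d`` the evaluation set holds all controls plus the
    adverse cases recorded within ``d`` days of delivery.  Rows with an
    empty case subset carry a NaN AUC and a flag instead of being dropped.
    """
    if pred.days_to_delivery is None:
        raise ParameterError("prediction set lacks days_to_delivery")
    days = np.asarray(pred.days_to_delivery)
    rows = []
    for d in day_thresholds:
        keep = (pred.labels == 0) | (days <= d)
        sub = PredictionSet(pred.scores[keep], pred.labels[keep])
        n_cases = int(sub.labels.sum())
        if n_cases == 0 or n_cases == len(sub.labels):
            rows.append({"max_days": d, "auc": np.nan, "n_cases": n_cases,
                         "n_controls": len(sub.labels) - n_cases,
                         "flag": "single-class subset"})
            continue
        rows.append({"max_days": d, "auc": auc_mann_whitney(sub),
                     "n_cases": n_cases,
                     "n_controls": len(sub.labels) - n_cases, "flag": ""})
    return pd.DataFrame(rows)
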