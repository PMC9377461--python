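"""Evaluation of binary risk classifiers.

Threshold-free discrimination (midrank Mann–Whitney AUC), the Youden-index
operating point, confusion-matrix metrics, net reclassification improvement
(NRI) between two thresholded models, and a two-fold cross-validation
harness in which each fold's cutoff is selected on the opposite fold and the
resulting metrics are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "NriResult",
    "auc",
    "youden_cutoff",
    "confusion_at_threshold",
    "metrics_from_confusion",
    "nri",
    "twofold_threshold_metrics",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a thresholded classifier: tp, fp, fn, tn (all >= 0)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_events(self) -> int:
        return self.tp + self.fn

    @property
    def n_nonevents(self) -> int:
        return self.fp + self.tn

    @property
    def n_predicted_positive(self) -> int:
        return self.tp + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricSet:
    """Discrimination metrics; undefined ratios are NaN, never 0."""

    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float = math.nan


@dataclass(frozen=True)
class NriResult:
    """Two-category net reclassification improvement of model B over A."""

    nri_event: float
    nri_nonevent: float
    nri_integrated: float
    z: float
    p_two_sided: float


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Midrank Mann–Whitney AUC (equals the trapezoidal ROC area)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    ranks = rankdata(scores)
    n1 = int(np.sum(labels == 1))
    n0 = labels.shape[0] - n1
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _threshold_scan(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Candidate thresholds (ascending unique scores) with the sensitivity
    and specificity of the rule ``score >= threshold`` at each."""
    thresholds = np.unique(scores)
    n1 = int(np.sum(labels == 1))
    n0 = labels.shape[0] - n1
    # counts of events/nonevents at each unique score, cumulated from the top
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    idx = np.searchsorted(s_sorted, thresholds, side="left")
    cum_events = np.concatenate([[0], np.cumsum(y_sorted == 1)])
    cum_nonevents = np.concatenate([[0], np.cumsum(y_sorted == 0)])
    tp = n1 - cum_events[idx]
    fp = n0 - cum_nonevents[idx]
    sens = tp / n1
    spec = (n0 - fp) / n0
    return thresholds, sens, spec


def youden_cutoff(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the observed score values with the rule
    ``score >= threshold`` -> predicted positive; ties in J are broken
    toward the lowest threshold (favouring sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    thresholds, sens, spec = _threshold_scan(scores, labels)
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return float(thresholds[best])


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionMatrix:
    """Confusion matrix of the rule ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
    )


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity, precision and F1 from counts.

    A metric whose denominator is zero is NaN (undefined), not zero.
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    if math.isnan(sens) or math.isnan(prec) or (prec + sens) == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricSet(sensitivity=sens, specificity=spec, precision=prec, f1=f1)


def nri(
    pred_a: Sequence[int], pred_b: Sequence[int], labels: Sequence[int]
) -> NriResult:
    """Two-category NRI of model B relative to model A.

    Events gain when B reclassifies them upward (A negative, B positive);
    non-events gain when B reclassifies them downward. The z statistic uses
    the standard multinomial variance of each component; components are
    independent across events and non-events.
    """
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    labels = np.asarray(labels)
    if not (pred_a.shape == pred_b.shape == labels.shape):
        raise ValueError("pred_a, pred_b and labels must have equal length")
    for arr, name in ((pred_a, "pred_a"), (pred_b, "pred_b")):
        if not np.all((arr == 0) | (arr == 1)):
            raise ValueError(f"{name} must be binary predictions")
    n_event = int(np.sum(labels == 1))
    n_nonevent = int(np.sum(labels == 0))
    if n_event == 0 or n_nonevent == 0:
        raise ValueError("both events and non-events are required")

    up = (pred_a == 0) & (pred_b == 1)
    down = (pred_a == 1) & (pred_b == 0)

    def component(sel: np.ndarray, n: int, gain_up: bool) -> tuple[float, float]:
        p_up = float(np.sum(up & sel)) / n
        p_down = float(np.sum(down & sel)) / n
        value = (p_up - p_down) if gain_up else (p_down - p_up)
        var = (p_up + p_down) / n - (p_up - p_down) ** 2 / n
        return value, var

    nri_e, var_e = component(labels == 1, n_event, gain_up=True)
    nri_ne, var_ne = component(labels == 0, n_nonevent, gain_up=False)
    total = nri_e + nri_ne
    var = var_e + var_ne
    if var > 0:
        z = total / math.sqrt(var)
        p = 2.0 * float(norm.sf(abs(z)))
    else:
        z, p = 0.0, 1.0
    return NriResult(
        nri_event=nri_e, nri_nonevent=nri_ne, nri_integrated=total, z=z, p_two_sided=p
    )


def twofold_threshold_metrics(
    scores: Sequence[float], labels: Sequence[int], fold: Sequence[int]
) -> tuple[MetricSet, ConfusionMatrix]:
    """Two-fold cross-validated thresholded evaluation.

    For each fold, the Youden cutoff is selected on the *other* fold and
    applied to this fold. Metrics (including the midrank AUC of each fold)
    are averaged arithmetically; the per-fold confusion tables are summed,
    which is how a pooled cross-table is conventionally reported.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    fold = np.asarray(fold)
    fold_ids = np.unique(fold)
    if fold_ids.shape[0] != 2:
        raise ValueError("exactly two folds are required")

    metric_rows = []
    total_cm = ConfusionMatrix(0, 0, 0, 0)
    for f in fold_ids:
        eval_sel = fold == f
        sel_sel = ~eval_sel
        cutoff = youden_cutoff(scores[sel_sel], labels[sel_sel])
        cm = confusion_at_threshold(scores[eval_sel], labels[eval_sel], cutoff)
        ms = metrics_from_confusion(cm)
        metric_rows.append(
            MetricSet(
                sensitivity=ms.sensitivity,
                specificity=ms.specificity,
                precision=ms.precision,
                f1=ms.f1,
                auc=auc(scores[eval_sel], labels[eval_sel]),
            )
        )
        total_cm = total_cm + cm

    mean = MetricSet(
        sensitivity=float(np.mean([m.sensitivity for m in metric_rows])),
        specificity=float(np.mean([m.specificity for m in metric_rows])),
        precision=float(np.mean([m.precision for m in metric_rows])),
        f1=float(np.mean([m.f1 for m in metric_rows])),
        auc=float(np.mean([m.auc for m in metric_rows])),
    )
    return mean, total_cm
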