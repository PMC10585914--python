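"""Segmentation metrics and the statistics used to compare runs.

Pixel-level F1 (harmonic mean of precision and recall) and IoU (Jaccard
index) on binarized masks, the uncertainty accuracy

    UA = (n_correct&certain + n_incorrect&uncertain) / n_pixels

under a threshold on the normalized uncertainty map, Student-t 95%
confidence intervals for per-image metric lists, and Welch's two-sample
t-test for comparing two models' per-image scores.  An instance-level
detection F1 (greedy IoU matching at 0.5) is provided as a secondary,
clearly named metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricSummary",
    "confusion_counts",
    "f1_score",
    "iou_score",
    "uncertainty_accuracy",
    "instance_detection_f1",
    "ci95",
    "welch_t_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    ci95_half_width: float
    n: int


def _as_bool(pred, truth):
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def confusion_counts(pred, truth) -> ConfusionCounts:
    pred, truth = _as_bool(pred, truth)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def f1_score(pred, truth) -> float:
    """2*tp / (2*tp + fp + fn); two empty masks count as perfect agreement."""
    c = confusion_counts(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def iou_score(pred, truth) -> float:
    """tp / (tp + fp + fn); two empty masks count as perfect agreement."""
    c = confusion_counts(pred, truth)
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def uncertainty_accuracy(pred, truth, normalized_uncertainty,
                         u_threshold: float = 0.5) -> float:
    """Fraction of pixels that are correct-and-certain or
    incorrect-and-uncertain; certainty means uncertainty < u_threshold."""
    if not 0.0 <= u_threshold <= 1.0:
        raise ValueError("u_threshold must be in [0, 1]")
    pred, truth = _as_bool(pred, truth)
    unc = np.asarray(normalized_uncertainty, dtype=float)
    if unc.shape != pred.shape:
        raise ValueError("uncertainty map shape mismatch")
    correct = pred == truth
    certain = unc < u_threshold
    good = np.sum(correct & certain) + np.sum(~correct & ~certain)
    return float(good) / pred.size


def instance_detection_f1(pred_labels, true_labels,
                          iou_threshold: float = 0.5) -> float:
    """Secondary metric: detection F1 with greedy one-to-one IoU matching."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    pred_ids = [i for i in np.unique(pred_labels) if i > 0]
    true_ids = [i for i in np.unique(true_labels) if i > 0]
    if not pred_ids and not true_ids:
        return 1.0
    pairs = []
    for pi in pred_ids:
        pm = pred_labels == pi
        for ti in true_ids:
            tm = true_labels == ti
            inter = np.sum(pm & tm)
            if inter == 0:
                continue
            iou = inter / np.sum(pm | tm)
            if iou >= iou_threshold:
                pairs.append((iou, pi, ti))
    pairs.sort(reverse=True)
    used_p, used_t = set(), set()
    tp = 0
    for _, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        tp += 1
    denom = len(pred_ids) + len(true_ids)
    return 2.0 * tp / denom if denom else 1.0


def ci95(values) -> MetricSummary:
    """Mean with Student-t 95% half-width  t_{0.975,n-1} * sd / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("ci95 needs at least two values")
    sd = values.std(ddof=1)
    tmul = stats.t.ppf(0.975, n - 1)
    return MetricSummary(float(values.mean()),
                         float(tmul * sd / np.sqrt(n)), int(n))


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, Welch-Satterthwaite dof, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / a.size, vb / b.size
    dof = (se2a + se2b) ** 2 / (
        se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1)
    )
    return float(res.statistic), float(dof), float(res.pvalue)
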