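"""Quantitative evaluation: confusion counts, the five scalar segmentation
metrics, pooled-pixel precision–recall curves, radar-plot percentage scaling,
relative-difference reporting, Kruskal–Wallis comparison and cross-validation
fold summaries.

Scalar metrics are derived from per-slice confusion counts and averaged over
slices (mean ± std), matching how segmentation results are conventionally
reported; a pooled-pixel aggregation is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PRCurve",
    "confusion",
    "scalar_metrics",
    "pr_curve",
    "radar_percentage",
    "relative_difference",
    "kruskal_wallis",
    "fold_summary",
]

METRIC_NAMES = ("dsc", "jaccard", "precision", "specificity", "sensitivity")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class MetricsReport:
    """Mean ± std of each scalar metric over slices, plus pooled PR-AUC."""

    mean: dict[str, float]
    std: dict[str, float]
    auc: float | None = None
    per_slice: dict[str, np.ndarray] = field(default_factory=dict)


def _as_binary(mask) -> np.ndarray:
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1, False, True))):
        raise ValueError("mask must be binary")
    return m.astype(bool)


def confusion(pred_mask, true_mask) -> ConfusionCounts:
    """Exact per-pixel TP/FP/FN/TN counts for two binary maps."""
    p = _as_binary(pred_mask)
    t = _as_binary(true_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def scalar_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Dice, Jaccard, precision, specificity and sensitivity from counts.

    Degenerate (0/0) cases: a slice with empty truth and empty prediction
    counts as perfect (1.0); empty truth with a non-empty prediction counts
    as 0. Specificity with no true negatives possible defaults to 1.
    """

    def ratio(num: int, den: int, empty_ok: bool) -> float:
        if den == 0:
            return 1.0 if empty_ok else 0.0
        return num / den

    return {
        "dsc": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, empty_ok=True),
        "jaccard": ratio(c.tp, c.tp + c.fp + c.fn, empty_ok=True),
        "precision": ratio(c.tp, c.tp + c.fp, empty_ok=c.fn == 0),
        "specificity": ratio(c.tn, c.tn + c.fp, empty_ok=True),
        "sensitivity": ratio(c.tp, c.tp + c.fn, empty_ok=c.fp == 0),
    }


def pr_curve(scores, truths) -> PRCurve:
    """Precision–recall over pooled pixels.

    Pixels are pooled across all maps and sorted by score; precision and
    recall are evaluated at every distinct threshold. The area under the
    curve is the trapezoid over recall, with the curve anchored at recall 0
    at the first achievable precision (the precision of the highest-score
    operating point).
    """
    s = np.concatenate([np.asarray(x, dtype=np.float64).ravel() for x in np.atleast_1d(scores)]) \
        if isinstance(scores, (list, tuple)) else np.asarray(scores, dtype=np.float64).ravel()
    t = np.concatenate([_as_binary(x).ravel() for x in truths]) \
        if isinstance(truths, (list, tuple)) else _as_binary(truths).ravel()
    if s.size == 0 or s.size != t.size:
        raise ValueError("scores and truths must be non-empty and equal-sized")
    n_pos = int(t.sum())
    if n_pos == 0:
        raise ValueError("PR curve undefined: no positive pixels in the truth maps")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    # Cumulative counts at each pixel, collapsed to distinct thresholds.
    tp_cum = np.cumsum(t_sorted)
    fp_cum = np.cumsum(~t_sorted)
    distinct = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    tp, fp = tp_cum[distinct], fp_cum[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    thresholds = s_sorted[distinct]
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    auc = float(np.trapezoid(p, r))
    return PRCurve(recall=r, precision=p, thresholds=thresholds, auc=auc)


def radar_percentage(x: float, max_value: float) -> float:
    """Rescale a metric so 0.5 maps to 0% and the column maximum to 100%."""
    if max_value <= 0.5:
        raise ValueError("max_value must exceed 0.5 for the percentage rescaling")
    return (x - 0.5) / (max_value - 0.5) * 100.0


def relative_difference(a: float, b: float) -> float:
    """Signed percent difference, 100*|a-b|/max(a,b): positive when `b`
    exceeds `a` ("higher than ours"), negative when `b` is lower."""
    if a <= 0 or b <= 0:
        raise ValueError("relative difference requires positive inputs")
    mag = 100.0 * abs(a - b) / max(a, b)
    return round(mag if b > a else (-mag if b < a else 0.0), 2)


def kruskal_wallis(groups: list[list[float]]) -> tuple[float, float]:
    """Rank-based H statistic with tie correction and its chi-square p-value.

    Backed by scipy; the all-identical-values degenerate case (H undefined by
    a 0/0 tie correction) is resolved to (0, 1) — no evidence of difference.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = spstats.kruskal(*arrays)
    return float(h), float(p)


def fold_summary(values: list[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) of per-fold metrics,
    rounded to 4 decimals for reporting."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("fold summary of an empty list")
    std = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return round(float(v.mean()), 4), round(std, 4)


def aggregate_reports(per_slice: dict[str, np.ndarray], auc: float | None = None) -> MetricsReport:
    """Assemble a MetricsReport from per-slice metric arrays."""
    mean = {k: float(np.mean(v)) for k, v in per_slice.items()}
    std = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in per_slice.items()}
    return MetricsReport(mean=mean, std=std, auc=auc, per_slice=per_slice)
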