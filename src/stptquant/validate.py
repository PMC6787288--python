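"""Voxel-wise validation of probability maps against reference masks.

Observer-drawn binary masks serve as the reference; the classifier's
probability map is binarized at a sweep of segmentation thresholds and
compared voxel by voxel.  For each threshold the four confusion counts and
the canonical rates (TPR, FNR = 1-TPR, FPR, TNR = 1-FPR), precision, F1 and
the Matthews Correlation Coefficient are reported, with the operating point
taken at 5% of the 8-bit range.  A seeded random-crop utility reproduces
subregion sampling of large sections, summarized as mean +/- SEM; and an
ordinary least-squares regression relates automated densities to manual
counts.

Zero-denominator conventions (documented in every report): F1 is NA when
TP + FP + FN = 0 (no positives anywhere); MCC is 0 when any confusion-matrix
marginal is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ProbabilityMap

__all__ = [
    "ConfusionCounts",
    "ConfusionMetrics",
    "ValidationReport",
    "RegressionResult",
    "confusion_at_threshold",
    "metrics_from_confusion",
    "threshold_sweep",
    "regress_counts",
    "random_crops",
    "crop_sweep_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-wise confusion counts at one segmentation threshold."""

    tp: int
    fp: int
    fn: int
    tn: int
    threshold_fraction: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class ConfusionMetrics(NamedTuple):
    tpr: float
    fpr: float
    precision: float
    f1: float
    mcc: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class ValidationReport:
    """Per-threshold confusion counts and metrics for one label, plus the
    5%-threshold operating point."""

    table: pd.DataFrame
    label_name: str
    operating_point: pd.Series

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def _as_probability(prob: ProbabilityMap | np.ndarray) -> np.ndarray:
    if isinstance(prob, ProbabilityMap):
        return prob.probabilities
    prob = np.asarray(prob, dtype=np.float64)
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probability values must lie in [0, 1]")
    return prob


def _as_binary(reference: np.ndarray) -> np.ndarray:
    ref = np.asarray(reference)
    vals = np.unique(ref)
    if ref.dtype == bool:
        return ref
    if set(vals.tolist()) <= {0, 1}:
        return ref.astype(bool)
    if set(vals.tolist()) <= {0, 255}:  # 8-bit binary mask convention
        return ref > 0
    raise ValueError("reference mask must be strictly binary (0/1 or 0/255)")


def confusion_at_threshold(
    reference: np.ndarray,
    prob: ProbabilityMap | np.ndarray,
    threshold_fraction: float,
) -> ConfusionCounts:
    """Binarize the probability map at ``p >= threshold_fraction`` and count
    TP/FP/FN/TN voxel-wise against a strictly binary reference."""
    ref = _as_binary(reference)
    p = _as_probability(prob)
    if ref.shape != p.shape:
        raise ValueError(f"shape mismatch: reference {ref.shape}, map {p.shape}")
    pred = p >= threshold_fraction
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    tn = int(np.count_nonzero(~pred & ~ref))
    return ConfusionCounts(tp, fp, fn, tn, threshold_fraction)


def metrics_from_confusion(c: ConfusionCounts) -> ConfusionMetrics:
    """Rates and summary scores from one confusion matrix.

    TPR = TP/(TP+FN), FPR = FP/(FP+TN) (reference-negative denominator),
    precision = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN),
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Degenerate denominators follow the module-level conventions.
    """
    tp, fp, fn, tn = (float(v) for v in (c.tp, c.fp, c.fn, c.tn))
    tpr = tp / (tp + fn) if tp + fn > 0 else math.nan
    fpr = fp / (fp + tn) if fp + tn > 0 else math.nan
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if tp + fp + fn > 0 else math.nan
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return ConfusionMetrics(tpr, fpr, precision, f1, mcc)


def threshold_sweep(
    reference: np.ndarray,
    prob: ProbabilityMap | np.ndarray,
    thresholds: Sequence[float],
    label_name: str = "",
    operating_threshold: float = 0.05,
) -> ValidationReport:
    """Confusion counts and metrics across a strictly increasing threshold
    sweep; the operating point is always evaluated at ``operating_threshold``
    (5% of the 8-bit range by default) whether or not it is in the sweep."""
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ValueError("threshold list must not be empty")
    if any(t < 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    rows = []
    for t in thresholds:
        c = confusion_at_threshold(reference, prob, t)
        m = metrics_from_confusion(c)
        rows.append(
            dict(
                threshold=t,
                tp=c.tp,
                fp=c.fp,
                fn=c.fn,
                tn=c.tn,
                tpr=m.tpr,
                fnr=1.0 - m.tpr if not math.isnan(m.tpr) else math.nan,
                fpr=m.fpr,
                tnr=1.0 - m.fpr if not math.isnan(m.fpr) else math.nan,
                precision=m.precision,
                f1=m.f1,
                mcc=m.mcc,
            )
        )
    table = pd.DataFrame(rows)
    c_op = confusion_at_threshold(reference, prob, operating_threshold)
    m_op = metrics_from_confusion(c_op)
    operating = pd.Series(
        dict(
            threshold=operating_threshold,
            tp=c_op.tp,
            fp=c_op.fp,
            fn=c_op.fn,
            tn=c_op.tn,
            tpr=m_op.tpr,
            fpr=m_op.fpr,
            precision=m_op.precision,
            f1=m_op.f1,
            mcc=m_op.mcc,
        )
    )
    return ValidationReport(table, label_name, operating)


def regress_counts(
    ml_values: Sequence[float], manual_counts: Sequence[float]
) -> RegressionResult:
    """Ordinary least squares (with intercept) of manual counts on automated
    values; returns slope, intercept, R^2 and the two-sided slope p-value.
    A constant response is reported as R^2 = 0 by convention."""
    x = np.asarray(ml_values, dtype=np.float64)
    y = np.asarray(manual_counts, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ml_values and manual_counts must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("regression requires at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("regression inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(x))
    res = stats.linregress(x, y)
    return RegressionResult(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
        len(x),
    )


def random_crops(
    shape: tuple[int, int, int],
    n_crops: int = 8,
    crop_pixels: int = 1_048_576,
    seed: int = 0,
) -> list[tuple[int, slice, slice]]:
    """Seeded random square 2-D subregions of ~``crop_pixels`` pixels.

    Returns ``(section_index, row_slice, col_slice)`` triples drawn uniformly
    over sections and positions.  Crops that happen to contain no reference-
    positive voxels are deliberately retained — negative-control subregions
    are meaningful.  Crops are clipped to the section size when a section is
    smaller than the requested area.
    """
    if n_crops < 1:
        raise ValueError("n_crops must be positive")
    ns, nr, nc = shape
    side = int(round(math.sqrt(crop_pixels)))
    side_r, side_c = min(side, nr), min(side, nc)
    rng = np.random.default_rng(seed)
    crops = []
    for _ in range(n_crops):
        s = int(rng.integers(0, ns))
        r0 = int(rng.integers(0, nr - side_r + 1))
        c0 = int(rng.integers(0, nc - side_c + 1))
        crops.append((s, slice(r0, r0 + side_r), slice(c0, c0 + side_c)))
    return crops


def crop_sweep_summary(
    reference: np.ndarray,
    prob: ProbabilityMap | np.ndarray,
    thresholds: Sequence[float],
    n_crops: int = 8,
    crop_pixels: int = 1_048_576,
    seed: int = 0,
    label_name: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-crop validation plus a mean +/- SEM summary per threshold.

    Returns ``(per_crop, summary)``: the first has one row per (crop,
    threshold); the second averages each metric over crops with its standard
    error, the form in which operating points are usually quoted.
    """
    ref = _as_binary(reference)
    p = _as_probability(prob)
    crops = random_crops(ref.shape, n_crops, crop_pixels, seed)
    per_rows = []
    for i, (s, rs, cs) in enumerate(crops):
        rep = threshold_sweep(ref[s, rs, cs], p[s, rs, cs], thresholds, label_name)
        t = rep.table.copy()
        t.insert(0, "crop", i)
        t.insert(1, "section", s)
        per_rows.append(t)
    per_crop = pd.concat(per_rows, ignore_index=True)
    metric_cols = ["tpr", "fnr", "fpr", "tnr", "precision", "f1", "mcc"]
    grouped = per_crop.groupby("threshold")[metric_cols]
    mean = grouped.mean()
    sem = grouped.sem()
    summary = mean.join(sem, lsuffix="_mean", rsuffix="_sem").reset_index()
    return per_crop, summary
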