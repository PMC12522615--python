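"""Segmentation evaluation: pixel confusion matrices, the seven agreement
metrics, image-level bootstrap 95% CIs, and the stage-distribution check.

Metrics are computed from pooled (micro-averaged) pixel counts. The
bootstrap resamples whole images with replacement (1,000 iterations by
default), pools the counts of each resample into one confusion matrix, and
reports the 2.5th / 97.5th percentiles of each metric's distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations_io import AnnotationScene, PolygonContour, rasterize

METRIC_NAMES = (
    "precision", "recall", "specificity", "f1", "accuracy", "dice", "jaccard",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts; tp+fp+fn+tn is the evaluated total."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The seven agreement metrics, each a proportion in [0, 1].

    An undefined metric (empty denominator) is NaN and is excluded from any
    aggregation by the caller.
    """

    precision: float
    recall: float
    specificity: float
    f1: float
    accuracy: float
    dice: float
    jaccard: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_from_masks(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts between two binary masks of equal shape."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return math.nan
    return num / den


def metrics_from_confusion(counts: ConfusionCounts) -> MetricSet:
    """Compute the seven metrics from pooled confusion counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN); specificity = TN/(TN+FP);
    F1 = 2PR/(P+R) = Dice = 2TP/(2TP+FP+FN); accuracy = (TP+TN)/total;
    Jaccard = TP/(TP+FP+FN).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    specificity = _ratio(tn, tn + fp, "specificity")
    dice = _ratio(2 * tp, 2 * tp + fp + fn, "dice")
    jaccard = _ratio(tp, tp + fp + fn, "jaccard")
    accuracy = (tp + tn) / counts.total
    # F1 from precision/recall equals Dice algebraically in the binary case
    f1 = dice
    return MetricSet(
        precision=precision, recall=recall, specificity=specificity,
        f1=f1, accuracy=accuracy, dice=dice, jaccard=jaccard,
    )


def multiclass_confusion(
    pred_scene: AnnotationScene, truth_scene: AnnotationScene, role: str
) -> ConfusionCounts:
    """Pooled confusion counts between two scenes for one annotation role.

    ``bone`` and ``cej`` are evaluated as a single binary mask per scene
    (both CEJ bands unioned); ``teeth`` is the 32-class task, evaluated as
    per-FDI one-vs-rest binary confusions summed over the classes present in
    either scene (micro-average). A tooth predicted with the wrong FDI label
    therefore counts as both a false positive (wrong class) and a false
    negative (missed true class).
    """
    if (pred_scene.image_width, pred_scene.image_height) != (
        truth_scene.image_width, truth_scene.image_height,
    ):
        raise ValueError("scene dimensions do not match")
    w, h = truth_scene.image_width, truth_scene.image_height

    def mask_of(contours: list[PolygonContour]) -> np.ndarray:
        out = np.zeros((h, w), dtype=bool)
        for ct in contours:
            out |= rasterize(ct, w, h)
        return out

    if role == "bone":
        pred = mask_of([pred_scene.bone] if pred_scene.bone else [])
        truth = mask_of([truth_scene.bone] if truth_scene.bone else [])
        return confusion_from_masks(pred, truth)
    if role == "cej":
        pred = mask_of(list(pred_scene.cej.values()))
        truth = mask_of(list(truth_scene.cej.values()))
        return confusion_from_masks(pred, truth)
    if role == "teeth":
        codes = sorted(set(pred_scene.teeth) | set(truth_scene.teeth))
        pooled = ConfusionCounts(0, 0, 0, 0)
        for code in codes:
            pred = mask_of([pred_scene.teeth[code]] if code in pred_scene.teeth else [])
            truth = mask_of(
                [truth_scene.teeth[code]] if code in truth_scene.teeth else []
            )
            pooled = pooled + confusion_from_masks(pred, truth)
        return pooled
    raise ValueError(f"unknown role {role!r} (expected bone, cej or teeth)")


@dataclass
class BootstrapResult:
    """Point estimates with percentile bootstrap CIs per metric."""

    point_estimate: MetricSet
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_iterations: int
    seed: int
    distributions: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def as_table(self) -> pd.DataFrame:
        rows = [
            {
                "metric": name,
                "estimate": getattr(self.point_estimate, name),
                "ci_low": self.ci_low[name],
                "ci_high": self.ci_high[name],
            }
            for name in METRIC_NAMES
        ]
        return pd.DataFrame(rows)


def bootstrap_ci(
    per_image_counts: Sequence[ConfusionCounts],
    n_iterations: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Image-level bootstrap of pooled segmentation metrics.

    Each iteration resamples the images with replacement (same size), pools
    the resampled confusion counts into one matrix, and computes the metric
    set; CI bounds are the 2.5th/97.5th percentiles of each metric's
    distribution (NaN replicates excluded with a warning). The point
    estimate is computed on the un-resampled pool.
    """
    if len(per_image_counts) == 0:
        raise ValueError("need at least one image to bootstrap")
    arr = np.array(
        [[c.tp, c.fp, c.fn, c.tn] for c in per_image_counts], dtype=np.int64
    )
    pooled = ConfusionCounts(*np.sum(arr, axis=0).tolist())
    point = metrics_from_confusion(pooled)

    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    samples = {name: np.empty(n_iterations) for name in METRIC_NAMES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-replicate undefined metrics
        for it in range(n_iterations):
            idx = rng.integers(0, n, size=n)
            tp, fp, fn, tn = np.sum(arr[idx], axis=0).tolist()
            ms = metrics_from_confusion(ConfusionCounts(tp, fp, fn, tn))
            for name in METRIC_NAMES:
                samples[name][it] = getattr(ms, name)

    ci_low: dict[str, float] = {}
    ci_high: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = samples[name]
        finite = vals[np.isfinite(vals)]
        if finite.size < vals.size:
            warnings.warn(
                f"{name}: {vals.size - finite.size} undefined bootstrap "
                "replicates excluded from the CI", stacklevel=2,
            )
        if finite.size == 0:
            ci_low[name] = math.nan
            ci_high[name] = math.nan
        else:
            ci_low[name] = float(np.percentile(finite, 2.5))
            ci_high[name] = float(np.percentile(finite, 97.5))
    return BootstrapResult(
        point_estimate=point, ci_low=ci_low, ci_high=ci_high,
        n_iterations=n_iterations, seed=seed, distributions=samples,
    )


def stage_distribution_test(
    counts_by_stage: Sequence[int],
) -> tuple[float, float]:
    """Pearson chi-square goodness-of-fit of stage counts against uniform.

    statistic = sum (observed - expected)^2 / expected with df = k - 1.
    Returns ``(statistic, p_value)``.
    """
    counts = np.asarray(counts_by_stage, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two stage categories")
    if np.any(counts < 0):
        raise ValueError("stage counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("stage counts sum to zero")
    result = stats.chisquare(counts)
    return float(result.statistic), float(result.pvalue)


def stage_shares(counts_by_stage: Sequence[int]) -> list[float]:
    """Percentage share of each stage (100 * count / total)."""
    counts = np.asarray(counts_by_stage, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("stage counts sum to zero")
    return [float(100.0 * c / total) for c in counts]
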