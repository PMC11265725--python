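"""Image- and pixel-level evaluation of tamper localization.

The positive class is "forged". From the confusion counts (tp = forged items
detected as forged, fn = forged missed, tn = authentic kept, fp = authentic
flagged) the module reports precision, recall, F1, sensitivity and
specificity, all as percentages. Sensitivity equals recall numerically; both
are reported because evaluation tables in this field conventionally print
both columns. Ratios with a zero denominator are reported as NaN — never
silently as zero — and NaN cells are excluded from table averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ConfusionCounts",
    "DetectionReport",
    "confusion",
    "scores",
    "f1_from_precision_recall",
    "image_verdict",
    "dataset_report",
    "truncate2",
]

_COLUMNS = ["precision", "recall", "f1", "specificity", "sensitivity"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with "forged" as the positive class."""

    tp: int  # forged, detected forged
    fn: int  # forged, labeled original
    tn: int  # original, kept original
    fp: int  # original, labeled forged

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.fp + other.fp,
        )


@dataclass(frozen=True)
class DetectionReport:
    """Metric percentages for one evaluation unit (image, pixel set, category)."""

    precision: float
    recall: float
    f1: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts | None = None


def confusion(predicted, truth) -> ConfusionCounts:
    """Confusion counts of predicted vs true binary labels (or masks)."""
    pred = np.asarray(predicted).astype(bool)
    true = np.asarray(truth).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    tp = int(np.count_nonzero(pred & true))
    fn = int(np.count_nonzero(~pred & true))
    tn = int(np.count_nonzero(~pred & ~true))
    fp = int(np.count_nonzero(pred & ~true))
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (all on the percent scale)."""
    if math.isnan(precision) or math.isnan(recall):
        return float("nan")
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def scores(counts: ConfusionCounts) -> DetectionReport:
    """Full metric family from confusion counts, as percentages.

    Undefined ratios (zero denominator) come back as NaN.
    """
    if counts.total == 0:
        raise ValueError("cannot score an empty confusion table")
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    specificity = _ratio(counts.tn, counts.tn + counts.fp)
    f1 = f1_from_precision_recall(precision, recall)
    return DetectionReport(
        precision=precision,
        recall=recall,
        f1=f1,
        sensitivity=recall,
        specificity=specificity,
        counts=counts,
    )


def image_verdict(mask: np.ndarray, min_region_pixels: int = 64) -> bool:
    """Image-level decision: forged iff some 8-connected mask component is
    at least ``min_region_pixels`` pixels (default 64 = one 8×8 block)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return False
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())[1:]
    return bool((sizes >= min_region_pixels).any())


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals; NaN passes through."""
    if math.isnan(x):
        return x
    return math.floor(x * 100.0) / 100.0


def dataset_report(
    per_category: Mapping[str, DetectionReport] | Sequence[tuple[str, ConfusionCounts]],
) -> pd.DataFrame:
    """Per-category metric table with an unweighted "Average" row.

    Accepts either a mapping category → :class:`DetectionReport` or a
    sequence of (category, counts) pairs, in which case counts are pooled per
    category and scored. Averages are computed at full precision over the
    category rows (NaN cells excluded) and truncated to two decimals.
    """
    if isinstance(per_category, Mapping):
        reports = dict(per_category)
    else:
        if len(per_category) == 0:
            raise ValueError("no evaluation items given")
        pooled: dict[str, ConfusionCounts] = {}
        for category, counts in per_category:
            if category in pooled:
                pooled[category] = pooled[category] + counts
            else:
                pooled[category] = counts
        reports = {cat: scores(cnt) for cat, cnt in pooled.items()}
    if not reports:
        raise ValueError("no evaluation items given")
    rows = {
        cat: [getattr(rep, col) for col in _COLUMNS] for cat, rep in reports.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_COLUMNS)
    avg = [truncate2(float(np.nanmean(df[col]))) if df[col].notna().any() else float("nan") for col in _COLUMNS]
    df.loc["Average"] = avg
    return df
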