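"""Segmentation evaluation: Dice, sensitivity, specificity, accuracy, and
pairwise percentage-point comparison tables between models.

All per-model numbers derive from one pooled pixel confusion tally
(TP, FP, TN, FN):

* Dice = 2*TP / (2*TP + FP + FN)  (equivalently 2|A∩B| / (|A|+|B|))
* sensitivity = TP / (TP + FN), specificity = TN / (TN + FP)
* accuracy = (TP + TN) / n

Comparison tables report signed percentage-point deltas
100 * (model - reference), rounded to 2 decimals.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SegMetrics",
    "ComparisonTable",
    "confusion_tally",
    "dice_coefficient",
    "dice_loss",
    "seg_metrics",
    "improvement_table",
]


@dataclasses.dataclass(frozen=True)
class SegMetrics:
    dice: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pixels: int

    def __post_init__(self):
        for name in ("dice", "sensitivity", "specificity", "accuracy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not set(vals.tolist()) <= {0, 1, 0.0, 1.0, False, True}:
        raise ValueError(f"{name} is not binary (values {vals[:10]})")
    return arr.astype(bool)


def confusion_tally(pred_mask: np.ndarray, gt_mask: np.ndarray) -> tuple[int, int, int, int]:
    """Exact (TP, FP, TN, FN) pixel counts for two binary masks of equal shape."""
    pred = _as_binary(pred_mask, "pred_mask")
    gt = _as_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    tn = int(np.sum(~pred & ~gt))
    fn = int(np.sum(~pred & gt))
    return tp, fp, tn, fn


def dice_coefficient(pred: np.ndarray, gt: np.ndarray, smooth: float = 0.0) -> float:
    """(2*|pred ∩ gt| + smooth) / (|pred| + |gt| + smooth).

    Accepts soft predictions: intersection and sums are computed on the raw
    values, reducing to the confusion-count formula on binary masks.  With
    smooth=0 and two empty masks the coefficient is defined as 1.0.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    num = 2.0 * float(np.sum(pred * gt)) + smooth
    den = float(np.sum(pred) + np.sum(gt)) + smooth
    if den == 0.0:
        return 1.0
    return num / den


def dice_loss(pred: np.ndarray, gt: np.ndarray, smooth: float = 1.0) -> float:
    """1 - soft Dice; the differentiable training counterpart lives in
    :func:`incunet.nn.soft_dice_loss`."""
    return 1.0 - dice_coefficient(pred, gt, smooth=smooth)


def seg_metrics(pred: np.ndarray, gt: np.ndarray) -> SegMetrics:
    """All four evaluation metrics from one confusion tally.

    A vacuous denominator (e.g. sensitivity with no positive ground-truth
    pixels) is defined as 1.0, with a warning.
    """
    tp, fp, tn, fn = confusion_tally(pred, gt)
    return metrics_from_tally(tp, fp, tn, fn)


def metrics_from_tally(tp: int, fp: int, tn: int, fn: int) -> SegMetrics:
    n = tp + fp + tn + fn

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} has an empty denominator; defining it as 1.0", stacklevel=3)
            return 1.0
        return num / den

    return SegMetrics(
        dice=ratio(2 * tp, 2 * tp + fp + fn, "dice"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        accuracy=ratio(tp + tn, n, "accuracy"),
        n_pixels=n,
    )


_TRIPLE_FIELDS = ("dice", "sensitivity", "specificity")


@dataclasses.dataclass(frozen=True)
class ComparisonTable:
    """Signed percentage-point deltas of every model against one reference."""

    reference_model: str
    rows: tuple[tuple[str, float, float, float], ...]  # (name, Δdice, Δsens, Δspec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(model=n, dice=d, sensitivity=s, specificity=p) for n, d, s, p in self.rows]
        ).set_index("model")


def _triple(value) -> tuple[float, float, float]:
    if isinstance(value, SegMetrics):
        return (value.dice, value.sensitivity, value.specificity)
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValueError("expected (dice, sensitivity, specificity)")
    return t


def improvement_table(
    models: Mapping[str, Sequence[float] | SegMetrics], reference: str
) -> ComparisonTable:
    """Percentage-point improvement of each model over ``reference``.

    Delta = 100 * (model value - reference value), sign preserved, rounded
    to 2 decimals for reporting.
    """
    if reference not in models:
        raise KeyError(f"unknown reference model {reference!r}; have {list(models)}")
    ref = _triple(models[reference])
    rows = []
    for name, value in models.items():
        if name == reference:
            continue
        vals = _triple(value)
        rows.append((name,) + tuple(round(100.0 * (v - r), 2) for v, r in zip(vals, ref)))
    return ComparisonTable(reference_model=reference, rows=tuple(rows))
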