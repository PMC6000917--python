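"""Pixelwise segmentation metrics and training-curve summaries.

Wound pixels are the positive class.  Precision = TP/(TP+FP) and
IoU = TP/(TP+FP+FN); both ignore true negatives, so they are invariant to
padding a scene with more background.  A training run is summarized by MaxIoU
(the maximum of the test-IoU curve) and mIoU (the mean of its stationary
tail, by default the last half of the logged points).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "precision",
    "iou",
    "sensitivity",
    "dsc",
    "summarize",
]


class ConfusionCounts(NamedTuple):
    n_tp: int
    n_fp: int
    n_fn: int
    n_tn: int


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between two binary masks."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def precision(c: ConfusionCounts) -> float | None:
    """TP / (TP + FP); None when nothing was predicted positive."""
    denom = c[0] + c[1]
    return None if denom == 0 else c[0] / denom


def iou(c: ConfusionCounts) -> float | None:
    """TP / (TP + FP + FN); None when prediction and truth are both empty."""
    denom = c[0] + c[1] + c[2]
    return None if denom == 0 else c[0] / denom


def sensitivity(c: ConfusionCounts) -> float | None:
    denom = c[0] + c[2]
    return None if denom == 0 else c[0] / denom


def dsc(c: ConfusionCounts) -> float | None:
    denom = 2 * c[0] + c[1] + c[2]
    return None if denom == 0 else 2 * c[0] / denom


def summarize(
    iou_values: Sequence[float],
    stationary_fraction: float = 0.5,
) -> tuple[float, float]:
    """(mIoU, MaxIoU) of a test-IoU curve.

    mIoU averages the final ``stationary_fraction`` of the logged points (the
    stationary tail of the curve); MaxIoU is the curve maximum.
    """
    values = np.asarray(list(iou_values), dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty IoU series")
    if not 0.0 < stationary_fraction <= 1.0:
        raise ValueError("stationary_fraction must lie in (0, 1]")
    n_tail = max(1, int(np.ceil(stationary_fraction * values.size)))
    return float(values[-n_tail:].mean()), float(values.max())
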