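"""Detection-error arithmetic and segmentation-quality metrics.

Key-point errors are signed column differences ``x_error = x_detected -
x_truth`` (pixels); CTR errors are signed ratio differences.  Summaries
aggregate the *absolute* per-case errors by default (signed means are
available as an option): per-model mean over the four key points, per-set
mean over models, grand mean over sets, and the deviation degree —
the grand mean as a percentage of the image width.  All aggregates are
rounded half-up at 4 decimals (2 for the percentage).

Segmentation metrics compare a predicted mask against a reference:
pixelwise accuracy, precision, recall, Dice, IoU, and HD95 — the
symmetric 95th-percentile Hausdorff distance between the two masks'
boundary pixel sets (Euclidean, pixels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .contours import boundary_pixel_set
from .errors import LungCTRError
from .mask_io import BinaryMask, Point
from .util import round_half_up


def x_error(detected: Point, truth: Point) -> int:
    """Signed column error of a detected key point, pixels."""
    return detected.x - truth.x


def ctr_error(computed: float, truth: float) -> float:
    """Signed CTR error (computed minus reference)."""
    return computed - truth


@dataclass
class ErrorReport:
    """Aggregated key-point error summary.

    Every aggregate is the arithmetic mean of its children, rounded
    half-up to 4 decimals; the deviation degree is the grand mean as a
    percentage of the image width, 2 decimals.
    """

    keypoint_means: Dict[Tuple[str, str], Tuple[float, float, float, float]]
    model_means: Dict[Tuple[str, str], float]
    set_means: Dict[str, float]
    grand_mean: float
    deviation_degree: float
    image_width: int
    signed: bool = False


def _mean4(values: Sequence[float]) -> float:
    return round_half_up(sum(values) / len(values), 4)


def aggregate_errors(
    table: Mapping[Tuple[str, str], Sequence[Sequence[float]]],
    image_width: int,
    signed: bool = False,
) -> ErrorReport:
    """Aggregate per-case key-point errors grouped by (model, set).

    ``table`` maps ``(model, set)`` to a sequence of per-case rows, each
    row holding the four key-point errors (D2', D3', E1, E2) in pixels.
    By default the absolute per-case values are averaged; ``signed=True``
    averages the raw signed values instead.
    """
    if not table:
        raise LungCTRError("empty error table")
    keypoint_means: Dict[Tuple[str, str], Tuple[float, ...]] = {}
    for group, rows in table.items():
        arr = np.asarray(rows, dtype=float)
        if arr.size == 0:
            raise LungCTRError(f"empty error group {group}")
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise LungCTRError(f"group {group} must be n_cases x 4 key-point errors")
        if not signed:
            arr = np.abs(arr)
        keypoint_means[group] = tuple(round_half_up(v, 4) for v in arr.mean(axis=0))
    return aggregate_keypoint_means(keypoint_means, image_width, signed=signed)


def aggregate_keypoint_means(
    keypoint_means: Mapping[Tuple[str, str], Sequence[float]],
    image_width: int,
    signed: bool = False,
) -> ErrorReport:
    """Derive per-model, per-set and grand means from per-key-point means.

    Entry point for reproducing published summary tables, whose leaf
    values are already per-key-point means.
    """
    if not keypoint_means:
        raise LungCTRError("empty key-point mean table")
    if image_width <= 0:
        raise LungCTRError("image_width must be positive")
    model_means = {g: _mean4(v) for g, v in keypoint_means.items()}
    sets = sorted({s for _, s in model_means}, key=str)
    set_means = {}
    for s in sets:
        vals = [m for (_, gs), m in model_means.items() if gs == s]
        if not vals:
            raise LungCTRError(f"empty set group {s}")
        set_means[s] = _mean4(vals)
    grand = _mean4(list(set_means.values()))
    deviation = round_half_up(grand / image_width * 100.0, 2)
    return ErrorReport(
        keypoint_means={g: tuple(v) for g, v in keypoint_means.items()},
        model_means=model_means,
        set_means=set_means,
        grand_mean=grand,
        deviation_degree=deviation,
        image_width=int(image_width),
        signed=signed,
    )


def combine_ctr_errors(err_t1: float, err_t2: float) -> float:
    """Two-set mean CTR error, rounded half-up to 4 decimals."""
    return round_half_up((err_t1 + err_t2) / 2.0, 4)


@dataclass
class SegMetrics:
    """Pixelwise segmentation scores; ``None`` marks an undefined ratio."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    dice: Optional[float]
    iou: Optional[float]
    hd95: float


def _hd95_directed(src: np.ndarray, dst: np.ndarray) -> float:
    tree = cKDTree(dst)
    d, _ = tree.query(src, k=1)
    return float(np.percentile(d, 95))


def seg_metrics(pred: BinaryMask, truth: BinaryMask) -> SegMetrics:
    """Compare a predicted mask against a reference mask.

    HD95 is symmetric: the larger of the two directed 95th-percentile
    boundary distances.  Ratios with an empty denominator (empty truth
    for recall, empty prediction for precision, ...) are reported as
    ``None`` rather than raising.
    """
    if pred.grid.shape != truth.grid.shape:
        raise LungCTRError(
            f"mask dimensions differ: {pred.grid.shape} vs {truth.grid.shape}")
    p, t = pred.grid, truth.grid
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    total = tp + fp + fn + tn

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    acc = ratio(tp + tn, total)
    prec = ratio(tp, tp + fp)
    rec = ratio(tp, tp + fn)
    dice = ratio(2 * tp, 2 * tp + fp + fn)
    iou = ratio(tp, tp + fp + fn)

    bp = np.argwhere(boundary_pixel_set(p))
    bt = np.argwhere(boundary_pixel_set(t))
    if bp.size == 0 and bt.size == 0:
        hd = 0.0
    elif bp.size == 0 or bt.size == 0:
        hd = math.inf
    else:
        hd = max(_hd95_directed(bp, bt), _hd95_directed(bt, bp))
    return SegMetrics(accuracy=acc, precision=prec, recall=rec, dice=dice, iou=iou, hd95=hd)
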