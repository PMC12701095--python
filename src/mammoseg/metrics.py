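"""Overlap metrics and detection evaluation.

Implements box/mask IoU, generalised IoU, the Dice coefficient and its soft
differentiable relaxation used as the training loss, and single-class average
precision / mAP over a range of IoU thresholds.

Boxes follow the inclusive pixel convention of :class:`~mammoseg.annotations.BBox`
(area = (xmax - xmin + 1) * (ymax - ymin + 1)), so box metrics agree exactly
with pixel-enumeration on integer grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotations import BBox

__all__ = [
    "Detection",
    "DetectionEvalResult",
    "box_iou",
    "mask_iou",
    "iou",
    "giou",
    "dice",
    "dice_loss",
    "average_precision",
    "mean_average_precision",
    "MAP_THRESHOLDS",
]

#: IoU thresholds for mAP@50:95 — 0.5 to 0.95 in steps of 0.05.
MAP_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    """A detector output: a box plus a confidence score in [0, 1]."""

    box: BBox
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class DetectionEvalResult:
    """Per-threshold average precision for the single 'mass' class."""

    ap_per_threshold: Mapping[float, float]
    n_classes: int = 1

    @property
    def map50(self) -> float:
        return self.ap_per_threshold[0.5]

    @property
    def map50_95(self) -> float:
        return float(np.mean(list(self.ap_per_threshold.values())))


# ---------------------------------------------------------------------------
# overlap metrics


def box_iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two inclusive pixel boxes."""
    iw = min(a.xmax, b.xmax) - max(a.xmin, b.xmin) + 1
    ih = min(a.ymax, b.ymax) - max(a.ymin, b.ymin) + 1
    inter = max(iw, 0) * max(ih, 0)
    union = a.area + b.area - inter
    return inter / union


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU of two binary masks; two empty masks agree perfectly (1.0)."""
    a, b = _binarize(a), _binarize(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(inter / union)


def iou(a, b) -> float:
    """Dispatch IoU on argument kind: two boxes or two same-shape masks."""
    if isinstance(a, BBox) and isinstance(b, BBox):
        return box_iou(a, b)
    if isinstance(a, BBox) or isinstance(b, BBox):
        raise TypeError("iou needs two boxes or two masks, not a mix")
    return mask_iou(a, b)


def giou(a: BBox, b: BBox) -> float:
    """Generalised IoU: IoU minus the hull fraction not covered by the union.

    The hull C is the minimal enclosing box of A and B; GIoU stays defined
    (and informative) for disjoint boxes, approaching -1 as they separate.
    """
    hull = BBox(
        min(a.xmin, b.xmin), min(a.ymin, b.ymin), max(a.xmax, b.xmax), max(a.ymax, b.ymax)
    )
    iw = min(a.xmax, b.xmax) - max(a.xmin, b.xmin) + 1
    ih = min(a.ymax, b.ymax) - max(a.ymin, b.ymin) + 1
    inter = max(iw, 0) * max(ih, 0)
    union = a.area + b.area - inter
    return inter / union - (hull.area - union) / hull.area


def _binarize(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating):
        return arr >= 0.5
    return arr.astype(bool)


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Hard Dice coefficient 2|X∩Y| / (|X|+|Y|).

    Float inputs (probability maps) are thresholded at 0.5 first.  Two empty
    masks score 1.0; empty vs non-empty scores 0.0.
    """
    x, y = _binarize(x), _binarize(y)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    inter = np.logical_and(x, y).sum()
    total = x.sum() + y.sum()
    if total == 0:
        return 1.0
    return float(2.0 * inter / total)


def dice_loss(p: np.ndarray, y: np.ndarray, eps: float = 1.0) -> float:
    """Soft Dice loss 1 - (2 Σ p·y + ε) / (Σ p + Σ y + ε).

    ``p`` is a probability map in [0, 1]; the smoothing ε keeps the loss
    defined (and its gradient finite) on empty masks.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shapes differ: {p.shape} vs {y.shape}")
    if p.min(initial=0.0) < 0 or p.max(initial=0.0) > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    num = 2.0 * (p * y).sum() + eps
    den = p.sum() + y.sum() + eps
    return float(1.0 - num / den)


# ---------------------------------------------------------------------------
# average precision


def _ap_from_pr(tp: np.ndarray, fp: np.ndarray, n_truth: int) -> float:
    """Area under the precision envelope of the cumulative PR curve."""
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / n_truth
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # prepend (0, 1) and take the running max of precision from the right
    mrec = np.concatenate(([0.0], recall, [recall[-1] if recall.size else 0.0]))
    mpre = np.concatenate(([1.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def _ap_101_point(tp: np.ndarray, fp: np.ndarray, n_truth: int) -> float:
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / n_truth
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    mpre = np.concatenate((precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    pts = []
    for r in np.linspace(0.0, 1.0, 101):
        above = mpre[:-1][recall >= r - 1e-12]
        pts.append(above.max() if above.size else 0.0)
    return float(np.mean(pts))


def average_precision(
    detections: Sequence[Sequence[Detection]],
    truths: Sequence[Sequence[BBox]],
    iou_threshold: float,
    interpolation: str = "all-point",
) -> float:
    """Single-class AP at one IoU threshold.

    Detections across all images are ranked by descending confidence (ties
    keep input order); each is matched greedily to the unmatched ground-truth
    box of its image with the highest IoU, counting a true positive when that
    IoU reaches the threshold.  AP integrates the precision envelope over
    recall (``interpolation='all-point'``) or samples it at 101 recall points
    (``'101-point'``).
    """
    if len(detections) != len(truths):
        raise ValueError("detections and truths must cover the same images")
    n_truth = sum(len(t) for t in truths)
    if n_truth == 0:
        raise ValueError("no ground-truth boxes anywhere: recall undefined")
    flat = [
        (det.confidence, img_idx, det)
        for img_idx, dets in enumerate(detections)
        for det in dets
    ]
    order = sorted(range(len(flat)), key=lambda k: (-flat[k][0], k))
    matched: list[set[int]] = [set() for _ in truths]
    tp = np.zeros(len(flat))
    fp = np.zeros(len(flat))
    for rank, k in enumerate(order):
        _, img_idx, det = flat[k]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(truths[img_idx]):
            if j in matched[img_idx]:
                continue
            v = box_iou(det.box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[img_idx].add(best_j)
            tp[rank] = 1
        else:
            fp[rank] = 1
    if len(flat) == 0:
        return 0.0
    if interpolation == "all-point":
        return _ap_from_pr(tp, fp, n_truth)
    if interpolation == "101-point":
        return _ap_101_point(tp, fp, n_truth)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_average_precision(
    detections: Sequence[Sequence[Detection]],
    truths: Sequence[Sequence[BBox]],
    thresholds: Sequence[float] = MAP_THRESHOLDS,
    interpolation: str = "all-point",
) -> DetectionEvalResult:
    """AP at every requested IoU threshold (single 'mass' class, so mAP = AP)."""
    aps = {
        float(t): average_precision(detections, truths, float(t), interpolation)
        for t in thresholds
    }
    return DetectionEvalResult(ap_per_threshold=aps, n_classes=1)
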