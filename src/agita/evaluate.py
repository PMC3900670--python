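"""Detection matching and evaluation metrics.

Predicted and ground-truth instance label stacks are matched greedily by
decreasing voxel overlap, one-to-one; a pair counts only when the overlap
is positive and either the predicted centroid falls inside the
ground-truth mask or the IoU reaches 0.25. On top of the resulting
TP/FN/FP counts, the usual recall/precision/F-measure, confusion-matrix
accuracy and misclassification-rate summaries are provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectionCounts",
    "match_detections",
    "detection_metrics",
    "table_metrics",
    "confusion_accuracy",
    "misclassification_rate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp
        )


def match_detections(
    pred: np.ndarray, gt: np.ndarray, iou_threshold: float = 0.25
) -> tuple[DetectionCounts, list[tuple[int, int]]]:
    """Greedy one-to-one matching of predicted to ground-truth instances.

    Returns counts and the matched (pred_label, gt_label) pairs. Merges
    are penalised: one prediction can claim at most one ground-truth
    object, so the second object it spans becomes a false negative.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")

    pred_labels = np.unique(pred)
    pred_labels = pred_labels[pred_labels > 0]
    gt_labels = np.unique(gt)
    gt_labels = gt_labels[gt_labels > 0]
    if len(pred_labels) == 0 or len(gt_labels) == 0:
        return DetectionCounts(0, len(gt_labels), len(pred_labels)), []

    both = (pred > 0) & (gt > 0)
    pairs = np.stack([pred[both], gt[both]], axis=1)
    (uniq, counts) = np.unique(pairs, axis=0, return_counts=True)

    pred_sizes = {int(l): int((pred == l).sum()) for l in pred_labels}
    gt_sizes = {int(l): int((gt == l).sum()) for l in gt_labels}
    centroids = {
        int(l): tuple(int(round(c)) for c in com)
        for l, com in zip(
            pred_labels,
            ndimage.center_of_mass(pred > 0, pred, index=pred_labels),
        )
    }

    # overlaps sorted by decreasing size; deterministic tie order by labels
    order = np.lexsort((uniq[:, 1], uniq[:, 0], -counts))
    taken_pred: set[int] = set()
    taken_gt: set[int] = set()
    matched: list[tuple[int, int]] = []
    for k in order:
        pl, gl = int(uniq[k, 0]), int(uniq[k, 1])
        if pl in taken_pred or gl in taken_gt:
            continue
        overlap = int(counts[k])
        iou = overlap / (pred_sizes[pl] + gt_sizes[gl] - overlap)
        centroid_inside = gt[centroids[pl]] == gl
        if overlap > 0 and (centroid_inside or iou >= iou_threshold):
            matched.append((pl, gl))
            taken_pred.add(pl)
            taken_gt.add(gl)
    tp = len(matched)
    return (
        DetectionCounts(tp, len(gt_labels) - tp, len(pred_labels) - tp),
        matched,
    )


def detection_metrics(c: DetectionCounts) -> tuple[float, float, float]:
    """Recall, precision and F-measure from detection counts.

    Degenerate inputs (no ground truth or no predictions) yield zeros
    with a warning rather than an exception, so batch evaluation over
    frames that may be empty does not abort.
    """
    if c.tp + c.fn == 0 or c.tp + c.fp == 0:
        log.warning("degenerate detection counts %s; metrics reported as 0", c)
        return (0.0, 0.0, 0.0)
    recall = c.tp / (c.tp + c.fn)
    precision = c.tp / (c.tp + c.fp)
    if precision + recall == 0:
        return (recall, precision, 0.0)
    f = 2.0 * precision * recall / (precision + recall)
    return (recall, precision, f)


def table_metrics(
    c: DetectionCounts, decimals: int = 3
) -> tuple[float, float, float]:
    """Recall, precision and F rounded the way results tables print them.

    Recall and precision are rounded to ``decimals`` first and the
    F-measure is computed from the rounded values — the convention used
    when a table's F column is derived from its printed recall/precision
    columns rather than from raw counts.
    """
    recall, precision, _ = detection_metrics(c)
    recall = round(recall, decimals)
    precision = round(precision, decimals)
    if precision + recall == 0:
        return (recall, precision, 0.0)
    f = round(2.0 * precision * recall / (precision + recall), decimals)
    return (recall, precision, f)


def confusion_accuracy(matrix: np.ndarray) -> float:
    """Overall classification rate: trace over total of a confusion matrix."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    total = m.sum()
    if total <= 0:
        raise ValueError("confusion matrix must have positive total")
    return float(np.trace(m) / total)


def misclassification_rate(n_wrong: int, n_total: int) -> float:
    """Percentage of misclassified objects, rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("total count must be positive")
    return round(100.0 * n_wrong / n_total, 1)
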