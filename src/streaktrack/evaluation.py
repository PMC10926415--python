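"""Score automatic annotations against ground truth.

Predictions and ground truths from the same image are matched greedily,
one-to-one, in descending prediction-score order on bounding-box IoU.
Matched pairs report IoU, and — for polyline-polyline pairs — the
polyline Hausdorff distance and the signed arc-length difference
(prediction minus truth).  Sweeping the prediction-score threshold over
the set of observed scores yields a precision-recall curve.

Conventions pinned here: matching requires IoU >= 0.5 by default;
precision is 1 when nothing is predicted; recall is 0 when there is no
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .geometry import Annotation, Polyline, bbox_iou, bbox_of, hausdorff_distance, polyline_length

__all__ = [
    "MatchResult",
    "PRPoint",
    "match_annotations",
    "annotation_metrics",
    "precision_recall_curve",
    "pr_curve_to_dataframe",
    "matches_to_dataframe",
]


@dataclass
class MatchResult:
    """One matched prediction/ground-truth pair and its quality metrics."""

    gt_index: int
    pred_index: int
    iou: float
    pred_score: Optional[float]
    hausdorff: Optional[float] = None
    length_diff: Optional[float] = None


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int


def annotation_metrics(match: MatchResult, pred: Annotation, gt: Annotation) -> MatchResult:
    """Fill the polyline-pair metrics of a match in place.

    Hausdorff distance and signed length difference (pred - truth) are
    only defined when both shapes are polylines; for mixed-kind matches
    (e.g. a circle prediction near a frame edge) they stay None.
    """
    if isinstance(pred.shape, Polyline) and isinstance(gt.shape, Polyline):
        match.hausdorff = hausdorff_distance(pred.shape, gt.shape)
        match.length_diff = polyline_length(pred.shape) - polyline_length(gt.shape)
    return match


def match_annotations(
    pred: Sequence[Annotation],
    gt: Sequence[Annotation],
    iou_threshold: float = 0.5,
) -> Tuple[List[MatchResult], List[int], List[int]]:
    """Greedy one-to-one matching of predictions to ground truths.

    Predictions are visited in descending score order (unscored
    predictions count as score 0; ties break by input order) and each
    takes the highest-IoU still-unmatched ground truth with IoU at or
    above the threshold.  Returns (matches, false-positive prediction
    indices, false-negative ground-truth indices).
    """
    pred_boxes = [bbox_of(a) for a in pred]
    gt_boxes = [bbox_of(a) for a in gt]
    order = sorted(range(len(pred)), key=lambda i: (-(pred[i].score or 0.0), i))
    taken = set()
    matches: List[MatchResult] = []
    for i in order:
        best_j, best_iou = None, iou_threshold
        for j in range(len(gt)):
            if j in taken:
                continue
            iou = bbox_iou(pred_boxes[i], gt_boxes[j])
            if iou > best_iou or (best_j is None and iou >= iou_threshold):
                best_j, best_iou = j, iou
        if best_j is not None:
            taken.add(best_j)
            matches.append(
                annotation_metrics(
                    MatchResult(best_j, i, best_iou, pred[i].score), pred[i], gt[best_j]
                )
            )
    matched_preds = {m.pred_index for m in matches}
    fp = [i for i in range(len(pred)) if i not in matched_preds]
    fn = [j for j in range(len(gt)) if j not in taken]
    return matches, fp, fn


def precision_recall_curve(
    preds_per_image: Sequence[Sequence[Annotation]],
    gt_per_image: Sequence[Sequence[Annotation]],
    iou_threshold: float = 0.5,
) -> List[PRPoint]:
    """PR curve over the sorted set of unique prediction scores.

    For each threshold (descending), predictions with score >= threshold
    are matched image by image and the pooled counts produce one point.
    Recall is non-increasing as the threshold rises.
    """
    if len(preds_per_image) != len(gt_per_image):
        raise ValueError("prediction and ground-truth image lists differ in length")
    scores = sorted(
        {a.score if a.score is not None else 0.0 for preds in preds_per_image for a in preds},
        reverse=True,
    )
    n_gt = sum(len(g) for g in gt_per_image)
    if not scores:
        return [PRPoint(threshold=1.0, precision=1.0, recall=0.0, tp=0, fp=0, fn=n_gt)]
    points = []
    for threshold in scores:
        tp = fp = fn = 0
        for preds, gts in zip(preds_per_image, gt_per_image):
            kept = [a for a in preds if (a.score if a.score is not None else 0.0) >= threshold]
            matches, fps, fns = match_annotations(kept, gts, iou_threshold)
            tp += len(matches)
            fp += len(fps)
            fn += len(fns)
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        points.append(PRPoint(threshold, precision, recall, tp, fp, fn))
    return points


def pr_curve_to_dataframe(points: Sequence[PRPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "threshold": p.threshold,
                "precision": p.precision,
                "recall": p.recall,
                "tp": p.tp,
                "fp": p.fp,
                "fn": p.fn,
            }
            for p in points
        ],
        columns=["threshold", "precision", "recall", "tp", "fp", "fn"],
    )


def matches_to_dataframe(matches: Sequence[MatchResult], filename: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "filename": filename,
                "gt_index": m.gt_index,
                "pred_index": m.pred_index,
                "iou": m.iou,
                "pred_score": m.pred_score,
                "hausdorff": m.hausdorff,
                "length_diff": m.length_diff,
            }
            for m in matches
        ],
        columns=["filename", "gt_index", "pred_index", "iou", "pred_score", "hausdorff", "length_diff"],
    )
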