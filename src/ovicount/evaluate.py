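"""Instance-level and count-level evaluation of segmentation output.

Predicted instances are matched one-to-one to ground-truth instances at an
IoU threshold tau by optimal assignment; matched pairs are true positives,
unmatched predictions false positives, unmatched truth false negatives.
The summary ratios follow the convention of star-convex segmentation
frameworks: precision = tp/(tp+fp), recall = tp/(tp+fn), and accuracy
(average precision at tau) = tp/(tp+fp+fn). Count-level agreement between
automated and manual counts is the R^2 of an ordinary least-squares fit
with intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult",
    "MetricSet",
    "CountAgreement",
    "instance_iou",
    "match_instances",
    "metrics",
    "count_r2",
    "masks_from_labels",
]


@dataclass(frozen=True)
class MatchResult:
    iou_thresh: float
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int, float], ...] = ()  # (pred_idx, gt_idx, iou)


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    accuracy: float
    degenerate: bool = False  # all ratios were 0/0 (empty prediction AND truth)


@dataclass(frozen=True)
class CountAgreement:
    r_squared: float
    slope: float
    intercept: float
    errors: tuple[float, ...]  # automated - manual, per well


def instance_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A∩B| / |A∪B|; symmetric; 0 for disjoint masks and for two empty masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a) + np.count_nonzero(b) - inter
    if union == 0:
        return 0.0
    return inter / union


def masks_from_labels(labels: np.ndarray) -> list[np.ndarray]:
    """Split an instance label mask (0 = background) into boolean masks."""
    labels = np.asarray(labels)
    return [labels == k for k in np.unique(labels) if k != 0]


def match_instances(
    pred: Sequence[np.ndarray],
    gt: Sequence[np.ndarray],
    iou_thresh: float = 0.5,
    method: str = "assignment",
) -> MatchResult:
    """One-to-one matching of predicted to ground-truth masks at tau.

    ``assignment`` (default) maximizes the number of matched pairs with
    IoU >= tau via the Hungarian algorithm on the thresholded IoU matrix,
    preferring higher total IoU among maximum-cardinality matchings;
    ``greedy`` matches pairs in descending IoU order.
    """
    if not 0.0 < iou_thresh <= 1.0:
        raise ValueError("iou_thresh must lie in (0, 1]")
    n_pred, n_gt = len(pred), len(gt)
    if n_pred == 0 or n_gt == 0:
        return MatchResult(iou_thresh, 0, n_pred, n_gt)
    iou = np.zeros((n_pred, n_gt))
    for i, pm in enumerate(pred):
        for j, gm in enumerate(gt):
            iou[i, j] = instance_iou(pm, gm)
    valid = iou >= iou_thresh

    pairs: list[tuple[int, int, float]] = []
    if method == "assignment":
        # cardinality dominates; the small IoU term breaks ties toward better overlap
        benefit = np.where(valid, 1.0 + 1e-3 * iou, 0.0)
        rows, cols = linear_sum_assignment(-benefit)
        for i, j in zip(rows, cols):
            if valid[i, j]:
                pairs.append((int(i), int(j), float(iou[i, j])))
    elif method == "greedy":
        order = np.dstack(np.unravel_index(np.argsort(-iou, axis=None), iou.shape))[0]
        used_p: set[int] = set()
        used_g: set[int] = set()
        for i, j in order:
            if valid[i, j] and i not in used_p and j not in used_g:
                pairs.append((int(i), int(j), float(iou[i, j])))
                used_p.add(int(i))
                used_g.add(int(j))
    else:
        raise ValueError(f"unknown matching method {method!r}")

    tp = len(pairs)
    return MatchResult(iou_thresh, tp, n_pred - tp, n_gt - tp, tuple(pairs))


def metrics(match: MatchResult) -> MetricSet:
    """Precision, recall and accuracy = tp/(tp+fp+fn) from a match result.

    Ratios that are 0/0 (no predictions and no truth at all) are reported
    as 1 by convention, with the ``degenerate`` flag set.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    degenerate = (tp + fp + fn) == 0
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    accuracy = tp / (tp + fp + fn) if not degenerate else 1.0
    return MetricSet(round(precision, 4), round(recall, 4), round(accuracy, 4), degenerate)


def count_r2(pairs: Sequence[tuple[float, float]]) -> CountAgreement:
    """R^2 of the OLS fit (with intercept) of automated on manual counts.

    ``pairs`` holds (automated, manual) per well; at least 3 pairs with
    nonzero variance in the manual counts are required.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (automated, manual) pairs")
    auto, manual = arr[:, 0], arr[:, 1]
    if np.ptp(manual) == 0 or np.ptp(auto) == 0:
        raise ValueError("degenerate variance: counts are constant")
    fit = sps.linregress(manual, auto)
    return CountAgreement(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        errors=tuple(float(e) for e in auto - manual),
    )


def evaluate_masks(
    pred_labels: np.ndarray, gt_labels: np.ndarray, iou_thresh: float = 0.5
) -> tuple[MatchResult, MetricSet]:
    """Match + metrics directly from two instance label masks."""
    match = match_instances(
        masks_from_labels(pred_labels), masks_from_labels(gt_labels), iou_thresh
    )
    return match, metrics(match)


def load_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
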