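"""Instance-segmentation and joint-classification metrics.

Implements the standard nuclei evaluation suite: Dice coefficient over
binary masks, the Aggregated Jaccard Index (AJI), panoptic quality with
its detection (DQ) and segmentation (SQ) factors, detection F1, and the
joint detection+classification score Fct used for per-type evaluation.

Conventions for degenerate inputs (both maps empty => perfect score) are
chosen so that a trivially correct prediction scores 1.0; they are noted
in each docstring and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "MetricsReport", "dice_coef", "aji",
           "match_instances", "panoptic_quality", "detection_f1",
           "classification_score", "evaluate_pair"]


@dataclass
class MatchResult:
    """Unique IoU>0.5 pairing between ground-truth and predicted instances."""

    pairs: list[tuple[int, int, float]]  # (gt_label, pred_label, IoU)
    unmatched_gt: list[int]              # detection false negatives
    unmatched_pred: list[int]            # detection false positives


@dataclass
class MetricsReport:
    dice: float
    aji: float
    dq: float
    sq: float
    pq: float
    fd: float
    fct_per_type: dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {"dice": self.dice, "aji": self.aji, "dq": self.dq,
               "sq": self.sq, "pq": self.pq, "fd": self.fd}
        out.update({f"fc{t}": v for t, v in self.fct_per_type.items()})
        return out


def _overlap_table(gt: np.ndarray, pred: np.ndarray):
    """Pairwise intersection counts plus per-instance areas, via a joint
    2-D histogram over (gt label, pred label)."""
    gt = np.asarray(gt).astype(np.int64)
    pred = np.asarray(pred).astype(np.int64)
    if gt.shape != pred.shape:
        raise ValueError("instance maps must share a shape")
    ng, npd = int(gt.max()), int(pred.max())
    joint = gt.ravel() * (npd + 1) + pred.ravel()
    counts = np.bincount(joint, minlength=(ng + 1) * (npd + 1))
    table = counts.reshape(ng + 1, npd + 1)  # [gt, pred] intersections
    gt_areas = table.sum(axis=1)
    pred_areas = table.sum(axis=0)
    return table, gt_areas, pred_areas, ng, npd


def dice_coef(x: np.ndarray, y: np.ndarray) -> float:
    """Dice coefficient 2|X∩Y| / (|X|+|Y|) over binary masks.

    Both masks empty => 1.0 (a perfect trivial prediction).
    """
    x = np.asarray(x) > 0
    y = np.asarray(y) > 0
    if x.shape != y.shape:
        raise ValueError("masks must share a shape")
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(x, y).sum() / denom)


def aji(gt: np.ndarray, pred: np.ndarray) -> float:
    """Aggregated Jaccard Index.

    In ascending ground-truth label order, each GT instance selects the
    not-yet-used prediction maximising its Jaccard index; intersections
    and unions accumulate over these pairs, and every never-selected
    prediction adds its full area to the union.  A GT instance with no
    overlapping unused prediction contributes its own area to the union.

    Empty GT and prediction => 1.0; empty GT with predictions => 0.0.
    """
    table, gt_areas, pred_areas, ng, npd = _overlap_table(gt, pred)
    if ng == 0:
        return 1.0 if npd == 0 else 0.0
    used = np.zeros(npd + 1, dtype=bool)
    inter_sum = 0
    union_sum = 0
    for g in range(1, ng + 1):
        overlaps = table[g, 1:]
        candidates = np.nonzero((overlaps > 0) & ~used[1:])[0]
        if candidates.size == 0:
            union_sum += int(gt_areas[g])
            continue
        inter = overlaps[candidates].astype(np.float64)
        union = gt_areas[g] + pred_areas[candidates + 1] - inter
        best = candidates[int(np.argmax(inter / union))]
        used[best + 1] = True
        inter_sum += int(overlaps[best])
        union_sum += int(gt_areas[g] + pred_areas[best + 1] - overlaps[best])
    union_sum += int(pred_areas[1:][~used[1:]].sum())
    if union_sum == 0:
        return 1.0
    return float(inter_sum / union_sum)


def match_instances(gt: np.ndarray, pred: np.ndarray) -> MatchResult:
    """Pair instances whose IoU exceeds 0.5 (such pairs are automatically
    unique) and list the unmatched labels on both sides."""
    table, gt_areas, pred_areas, ng, npd = _overlap_table(gt, pred)
    pairs = []
    matched_gt, matched_pred = set(), set()
    gs, ps = np.nonzero(table[1:, 1:] > 0)
    for g, p in zip(gs + 1, ps + 1):
        inter = float(table[g, p])
        iou = inter / float(gt_areas[g] + pred_areas[p] - inter)
        if iou > 0.5:
            pairs.append((int(g), int(p), iou))
            matched_gt.add(int(g))
            matched_pred.add(int(p))
    unmatched_gt = [g for g in range(1, ng + 1)
                    if g not in matched_gt and gt_areas[g] > 0]
    unmatched_pred = [p for p in range(1, npd + 1)
                      if p not in matched_pred and pred_areas[p] > 0]
    return MatchResult(pairs, unmatched_gt, unmatched_pred)


def panoptic_quality(gt: np.ndarray, pred: np.ndarray,
                     match: MatchResult | None = None) -> tuple[float, float, float]:
    """(DQ, SQ, PQ): detection quality, segmentation quality, and their
    product.  DQ = |TP| / (|TP| + |FP|/2 + |FN|/2); SQ = mean IoU over
    matched pairs (0 when there are none).  Both maps empty => (1,1,1).
    """
    if match is None:
        match = match_instances(gt, pred)
    tp = len(match.pairs)
    fp = len(match.unmatched_pred)
    fn = len(match.unmatched_gt)
    if tp + fp + fn == 0:
        logger.info("panoptic_quality on two empty maps: scoring (1,1,1)")
        return 1.0, 1.0, 1.0
    dq = tp / (tp + 0.5 * fp + 0.5 * fn)
    sq = float(np.mean([iou for _, _, iou in match.pairs])) if tp else 0.0
    return float(dq), sq, float(dq * sq)


def detection_f1(match: MatchResult) -> float:
    """Instance-detection F1 = 2TP / (2TP + FP + FN) over the matching."""
    tp = len(match.pairs)
    fp = len(match.unmatched_pred)
    fn = len(match.unmatched_gt)
    if tp + fp + fn == 0:
        return 1.0
    return float(2 * tp / (2 * tp + fp + fn))


def classification_score(match: MatchResult, gt_types: dict[int, int],
                         pred_types: dict[int, int], type_t: int) -> float:
    """Joint detection+classification score for nucleus type ``type_t``.

    Over matched pairs: TPc = both typed t; TNc = neither typed t;
    FPc = predicted t but GT not t; FNc = GT t but predicted otherwise.
    Fct = 2(TPc+TNc) / (2(TPc+TNc) + 2(FPc+FNc) + FPd + FNd), where
    FPd/FNd are detection false positives/negatives.  An all-empty
    evaluation (no instances anywhere) scores 1.0.
    """
    tpc = tnc = fpc = fnc = 0
    for g, p, _ in match.pairs:
        gt_is_t = gt_types[g] == type_t
        pred_is_t = pred_types[p] == type_t
        if gt_is_t and pred_is_t:
            tpc += 1
        elif not gt_is_t and not pred_is_t:
            tnc += 1
        elif pred_is_t:
            fpc += 1
        else:
            fnc += 1
    fpd = len(match.unmatched_pred)
    fnd = len(match.unmatched_gt)
    denom = 2 * (tpc + tnc) + 2 * (fpc + fnc) + fpd + fnd
    if denom == 0:
        logger.info("classification_score with no instances: scoring 1.0")
        return 1.0
    return float(2 * (tpc + tnc) / denom)


def evaluate_pair(gt: np.ndarray, pred: np.ndarray,
                  gt_types: dict[int, int] | None = None,
                  pred_types: dict[int, int] | None = None,
                  n_types: int = 0) -> MetricsReport:
    """Full report for one image: Dice/AJI/DQ/SQ/PQ/Fd and, when type
    assignments are supplied, Fct per type."""
    match = match_instances(gt, pred)
    dq, sq, pq = panoptic_quality(gt, pred, match)
    report = MetricsReport(
        dice=dice_coef(gt > 0, pred > 0),
        aji=aji(gt, pred),
        dq=dq, sq=sq, pq=pq,
        fd=detection_f1(match),
    )
    if gt_types is not None and pred_types is not None:
        for t in range(1, n_types + 1):
            report.fct_per_type[t] = classification_score(
                match, gt_types, pred_types, t)
    return report
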