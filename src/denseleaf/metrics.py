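"""Detection metrics: precision, recall, F1, AP/mAP and COCO-style summaries.

AP integrates precision over recall, AP = ∫ P(R) dR. The operative dialect
here is the COCO one — 101-point interpolation of the precision envelope,
mAP averaged over IoU thresholds 0.50:0.05:0.95, fixed-threshold mAP@50 and
mAP@75, and AR@K (best recall when each image may contribute at most K
detections, averaged over the same IoU grid). The literal trapezoid integral
is available as an optional interpolation mode. There is a single foreground
category ("leaf"), so the class average in mAP is over one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .boxes import BoundingBox, ScoredBox, iou_matrix

__all__ = ["APSummary", "greedy_match", "ap_from_ranked_flags", "summarize",
           "COCO_IOU_THRESHOLDS"]

COCO_IOU_THRESHOLDS: np.ndarray = np.round(np.arange(0.50, 0.96, 0.05), 2)


@dataclass(frozen=True)
class APSummary:
    """One evaluation run; all values in [0, 1] (multiply by 100 to report %)."""

    map: float
    map50: float
    map75: float
    ar100: float
    ar300: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mAP": self.map, "mAP@50": self.map50, "mAP@75": self.map75,
            "AR@100": self.ar100, "AR@300": self.ar300,
            "precision": self.precision, "recall": self.recall, "F1": self.f1,
        }

    def to_table(self) -> str:
        """Plain-text row mirroring the usual detection-benchmark columns."""
        head = f"{'mAP':>8}{'mAP@50':>9}{'mAP@75':>9}{'AR@100':>9}{'AR@300':>9}"
        row = (f"{self.map * 100:7.1f}%{self.map50 * 100:8.1f}%"
               f"{self.map75 * 100:8.1f}%{self.ar100 * 100:8.1f}%"
               f"{self.ar300 * 100:8.1f}%")
        return head + "\n" + row


def _sorted_indices(detections: Sequence[ScoredBox]) -> list[int]:
    # descending score, ties toward the lower original index
    return sorted(range(len(detections)), key=lambda i: (-detections[i].score, i))


def greedy_match(detections: Sequence[ScoredBox],
                 ground_truths: Sequence[BoundingBox],
                 iou_threshold: float,
                 max_dets: int | None = None) -> tuple[np.ndarray, int]:
    """COCO-convention greedy matching inside one image.

    Detections are visited in descending score order (capped at ``max_dets``);
    each takes the unmatched ground truth of highest IoU and is a true
    positive iff that IoU reaches ``iou_threshold``. Each ground truth matches
    at most once. Returns the TP/FP flags *in visit order* and the count of
    unmatched ground truths (false negatives).
    """
    order = _sorted_indices(detections)
    if max_dets is not None:
        order = order[:max_dets]
    if not order or not ground_truths:
        return np.zeros(len(order), dtype=bool), len(ground_truths)
    ious = iou_matrix([detections[i] for i in order], ground_truths)
    gt_taken = np.zeros(len(ground_truths), dtype=bool)
    flags = np.zeros(len(order), dtype=bool)
    for row in range(len(order)):
        candidates = np.where(~gt_taken)[0]
        if candidates.size == 0:
            break
        best = candidates[np.argmax(ious[row, candidates])]
        if ious[row, best] >= iou_threshold:
            flags[row] = True
            gt_taken[best] = True
    fn = int((~gt_taken).sum())
    return flags, fn


def ap_from_ranked_flags(flags: Sequence[bool], num_gt: int,
                         interpolation: str = "101point") -> float:
    """Average precision from score-ranked TP/FP flags.

    ``101point``: the COCO dialect — the precision envelope (max precision at
    recall >= r) sampled at r in {0, 0.01, ..., 1.00} and averaged.
    ``continuous``: the literal area under the envelope.
    """
    if num_gt < 0:
        raise ValueError("num_gt must be >= 0")
    flags = np.asarray(flags, dtype=bool)
    if num_gt == 0:
        return 0.0
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / num_gt
    precision = tp / (tp + fp)
    # right-to-left running max = precision envelope
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "101point":
        grid = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(recall, grid, side="left")
        valid = idx < recall.size
        sampled = np.where(valid, envelope[np.minimum(idx, recall.size - 1)], 0.0)
        return float(sampled.mean())
    if interpolation == "continuous":
        r_prev = np.concatenate([[0.0], recall[:-1]])
        return float(np.sum((recall - r_prev) * envelope))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def _flags_global(dets_per_image: Mapping, gts_per_image: Mapping,
                  iou_thr: float, max_dets: int | None) -> tuple[np.ndarray, int, int]:
    """Per-image matching merged into a single global score ranking."""
    records: list[tuple[float, int, int, bool]] = []  # (-score, img_rank, det_rank, flag)
    total_gt = 0
    total_tp = 0
    for img_rank, img_id in enumerate(sorted(gts_per_image)):
        gts = gts_per_image[img_id]
        dets = dets_per_image.get(img_id, [])
        total_gt += len(gts)
        flags, _ = greedy_match(dets, gts, iou_thr, max_dets)
        order = _sorted_indices(dets)
        if max_dets is not None:
            order = order[:max_dets]
        for det_rank, (i, f) in enumerate(zip(order, flags)):
            records.append((-dets[i].score, img_rank, det_rank, bool(f)))
        total_tp += int(flags.sum())
    records.sort()
    return np.array([r[3] for r in records], dtype=bool), total_gt, total_tp


def summarize(dets_per_image: Mapping, gts_per_image: Mapping,
              score_threshold: float = 0.5,
              ap_max_dets: int = 100,
              interpolation: str = "101point") -> APSummary:
    """Full evaluation of per-image detections against per-image ground truth.

    Parameters
    ----------
    dets_per_image : mapping image id -> list of ScoredBox. Every image id
        must also appear in ``gts_per_image``.
    gts_per_image : mapping image id -> list of BoundingBox (possibly empty).
    score_threshold : operating point for the standalone precision/recall/F1
        (evaluated at IoU 0.5).
    ap_max_dets : per-image detection cap used inside the AP computation.
    """
    unknown = set(dets_per_image) - set(gts_per_image)
    if unknown:
        raise ValueError(f"detections reference unknown image ids: {sorted(unknown)!r}")

    aps = []
    for thr in COCO_IOU_THRESHOLDS:
        flags, num_gt, _ = _flags_global(dets_per_image, gts_per_image, thr, ap_max_dets)
        aps.append(ap_from_ranked_flags(flags, num_gt, interpolation))
    map50 = aps[0]
    map75 = aps[5]
    mean_ap = float(np.mean(aps)) if aps else 0.0

    def avg_recall(budget: int) -> float:
        recalls = []
        for thr in COCO_IOU_THRESHOLDS:
            _, num_gt, tp = _flags_global(dets_per_image, gts_per_image, thr, budget)
            recalls.append(tp / num_gt if num_gt else 0.0)
        return float(np.mean(recalls))

    ar100 = avg_recall(100)
    ar300 = avg_recall(300)

    # operating-point precision / recall / F1 at IoU 0.5
    tp = fp = fn = 0
    for img_id in sorted(gts_per_image):
        dets = [d for d in dets_per_image.get(img_id, []) if d.score >= score_threshold]
        flags, img_fn = greedy_match(dets, gts_per_image[img_id], 0.5)
        tp += int(flags.sum())
        fp += int((~flags).sum())
        fn += img_fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    return APSummary(mean_ap, map50, map75, ar100, ar300, precision, recall, f1)
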