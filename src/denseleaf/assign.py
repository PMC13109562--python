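"""Prediction-to-ground-truth matching for set-based detection training.

One-to-one matching is the classical minimum-cost bipartite (Hungarian)
assignment over a DETR-convention cost

    cost[p, g] = w_cls * (1 - prob_p) + w_l1 * ||b_p - b_g||_1 + w_giou * (1 - GIoU(b_p, b_g))

with boxes in normalized center form. The crowded-scene refinements are:

* **Top-K Hungarian matching** — each ground truth is effectively replicated
  ``k`` times; matching proceeds in ``k`` sequential one-to-one rounds, and a
  prediction assigned in an earlier round is removed from the pool before the
  next round, so ``|pairs| = min(k * G, P)`` and every ground truth collects
  up to ``k`` predictions.
* **Crowded query refinement (CQR)** — the original decoder queries are first
  culled by class-agnostic NMS (duplicate queries on one leaf collapse to the
  highest-scoring one) and then matched one-to-one; a separate pool of extra
  queries is score-sorted and matched one-to-many with Top-K Hungarian, under
  a down-weighted loss. The extra branch exists only during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .boxes import (BoundingBox, ScoredBox, as_box_array, box_to_center_form,
                    class_agnostic_nms, giou_matrix)

__all__ = ["CostWeights", "MatchConfig", "CostMatrix", "Assignment",
           "build_cost_matrix", "hungarian_match", "topk_hungarian_match",
           "cqr_compose", "combined_loss"]


@dataclass(frozen=True)
class CostWeights:
    """DETR-family cost weights (classification, L1 box, GIoU)."""

    w_cls: float = 2.0
    w_l1: float = 5.0
    w_giou: float = 2.0


@dataclass(frozen=True)
class MatchConfig:
    """Configuration of the CQR matcher.

    k : ground-truth replication factor of the one-to-many branch (1-8;
        4 gives the best trade-off between supervision density and noise).
    nms_threshold : IoU above which duplicate original queries are culled.
    extra_loss_weight : multiplier on the extra-branch loss.
    """

    k: int = 4
    nms_threshold: float = 0.7
    extra_loss_weight: float = 0.5
    weights: CostWeights = field(default_factory=CostWeights)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.extra_loss_weight < 0:
            raise ValueError("extra_loss_weight must be >= 0")


@dataclass
class CostMatrix:
    """P x G matching costs plus the weights that built them."""

    values: np.ndarray
    weights: CostWeights = field(default_factory=CostWeights)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("cost matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cost matrix has non-finite entries")

    @property
    def num_predictions(self) -> int:
        return self.values.shape[0]

    @property
    def num_ground_truths(self) -> int:
        return self.values.shape[1]


@dataclass
class Assignment:
    """Chosen (prediction index, ground-truth index) pairs and their total cost."""

    pairs: list[tuple[int, int]]
    total_cost: float

    def prediction_indices(self) -> list[int]:
        return [p for p, _ in self.pairs]

    def ground_truth_indices(self) -> list[int]:
        return [g for _, g in self.pairs]


def _center_to_corner(b: np.ndarray) -> np.ndarray:
    out = np.empty_like(b)
    out[:, 0] = b[:, 0] - b[:, 2] / 2
    out[:, 1] = b[:, 1] - b[:, 3] / 2
    out[:, 2] = b[:, 0] + b[:, 2] / 2
    out[:, 3] = b[:, 1] + b[:, 3] / 2
    return out


def build_cost_matrix(pred_boxes: np.ndarray, pred_probs: np.ndarray,
                      gt_boxes: np.ndarray,
                      weights: CostWeights | None = None) -> CostMatrix:
    """Cost matrix between predictions and ground truths.

    Parameters
    ----------
    pred_boxes : (P, 4) normalized center-form boxes (cx, cy, w, h).
    pred_probs : (P,) foreground class probabilities in [0, 1].
    gt_boxes : (G, 4) normalized center-form boxes; G may be 0.
    """
    weights = weights or CostWeights()
    pred_boxes = np.atleast_2d(np.asarray(pred_boxes, dtype=float))
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    pred_probs = np.asarray(pred_probs, dtype=float).ravel()
    if pred_boxes.shape[0] == 0:
        raise ValueError("prediction set is empty")
    if pred_boxes.shape[0] != pred_probs.shape[0]:
        raise ValueError(
            f"{pred_boxes.shape[0]} boxes vs {pred_probs.shape[0]} scores"
        )
    P, G = pred_boxes.shape[0], gt_boxes.shape[0]
    if G == 0:
        return CostMatrix(np.zeros((P, 0)), weights)
    cls_cost = (1.0 - pred_probs)[:, None]                       # (P, 1)
    l1_cost = np.abs(pred_boxes[:, None, :] - gt_boxes[None, :, :]).sum(-1)
    giou_cost = 1.0 - giou_matrix(_center_to_corner(pred_boxes),
                                  _center_to_corner(gt_boxes))
    values = (weights.w_cls * cls_cost + weights.w_l1 * l1_cost
              + weights.w_giou * giou_cost)
    return CostMatrix(values, weights)


def hungarian_match(cost: CostMatrix) -> Assignment:
    """Minimum-cost one-to-one assignment of min(P, G) pairs."""
    if cost.num_ground_truths == 0 or cost.num_predictions == 0:
        return Assignment([], 0.0)
    rows, cols = linear_sum_assignment(cost.values)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    total = float(cost.values[rows, cols].sum())
    return Assignment([tuple(p) for p in pairs], total)


def topk_hungarian_match(cost: CostMatrix, k: int) -> Assignment:
    """One-to-many matching: k sequential Hungarian rounds over a shrinking pool.

    Round r solves a fresh one-to-one problem restricted to the predictions
    not yet assigned in rounds 1..r-1; each ground truth therefore gathers at
    most one prediction per round, k overall. ``|pairs| = min(k * G, P)``.
    Reduces to :func:`hungarian_match` when k = 1.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    P = cost.num_predictions
    pairs: list[tuple[int, int]] = []
    total = 0.0
    available = np.arange(P)
    for _ in range(k):
        if available.size == 0 or cost.num_ground_truths == 0:
            break
        sub = CostMatrix(cost.values[available], cost.weights)
        round_assign = hungarian_match(sub)
        chosen = []
        for p_sub, g in round_assign.pairs:
            pairs.append((int(available[p_sub]), g))
            chosen.append(p_sub)
        total += round_assign.total_cost
        available = np.delete(available, chosen)
    return Assignment(sorted(pairs), total)


def _scored_to_arrays(queries: Sequence[ScoredBox],
                      image_size: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    w, h = image_size
    boxes = np.stack([box_to_center_form(q.box, w, h) for q in queries])
    probs = np.array([q.score for q in queries])
    return boxes, probs


def cqr_compose(original_queries: Sequence[ScoredBox],
                extra_queries: Sequence[ScoredBox],
                ground_truths: Sequence[BoundingBox],
                config: MatchConfig,
                image_size: tuple[float, float]) -> tuple[Assignment, Assignment]:
    """Crowded query refinement: culled one-to-one originals + Top-K extras.

    Originals pass through class-agnostic NMS first, so near-duplicate queries
    on the same leaf never compete inside the Hungarian solver; the returned
    pair indices refer to positions in the original, unculled list. Extras
    are ranked by classification score (no NMS) and matched one-to-many.
    With no extras the result reduces to NMS followed by plain one-to-one
    matching.
    """
    w, h = image_size
    gt_arr = (np.stack([box_to_center_form(g, w, h) for g in ground_truths])
              if len(ground_truths) else np.zeros((0, 4)))

    if original_queries:
        kept = class_agnostic_nms(original_queries, config.nms_threshold)
        kept_sorted = sorted(kept)
        boxes, probs = _scored_to_arrays([original_queries[i] for i in kept_sorted],
                                         image_size)
        cost_ori = build_cost_matrix(boxes, probs, gt_arr, config.weights)
        sub_assign = hungarian_match(cost_ori)
        assign_ori = Assignment(
            sorted((kept_sorted[p], g) for p, g in sub_assign.pairs),
            sub_assign.total_cost,
        )
    else:
        assign_ori = Assignment([], 0.0)

    if extra_queries:
        order = sorted(range(len(extra_queries)),
                       key=lambda i: (-extra_queries[i].score, i))
        boxes, probs = _scored_to_arrays([extra_queries[i] for i in order], image_size)
        cost_extra = build_cost_matrix(boxes, probs, gt_arr, config.weights)
        sub_assign = topk_hungarian_match(cost_extra, config.k)
        assign_extra = Assignment(
            sorted((order[p], g) for p, g in sub_assign.pairs),
            sub_assign.total_cost,
        )
    else:
        assign_extra = Assignment([], 0.0)

    return assign_ori, assign_extra


def combined_loss(loss_ori: float, loss_extra: float, extra_weight: float) -> float:
    """Dual-branch objective: original loss plus down-weighted extra loss."""
    if extra_weight < 0:
        raise ValueError("extra branch weight must be >= 0")
    if loss_ori < 0 or loss_extra < 0:
        raise ValueError("losses must be >= 0")
    return loss_ori + extra_weight * loss_extra
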