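"""Axis-aligned box primitives, overlap measures and class-agnostic NMS.

Boxes live in continuous pixel coordinates with the origin at the top-left
corner, stored corner-form ``(x_min, y_min, x_max, y_max)``. Area is the plain
product ``(x_max - x_min) * (y_max - y_min)`` with no +1 correction, matching
the COCO convention the metrics module reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BoundingBox",
    "ScoredBox",
    "as_box_array",
    "box_iou",
    "box_giou",
    "iou_matrix",
    "giou_matrix",
    "class_agnostic_nms",
    "convert_box",
    "box_to_center_form",
    "xywh_to_xyxy",
    "xyxy_to_xywh",
]


@dataclass(frozen=True)
class BoundingBox:
    """A corner-form box; invariant ``x_max >= x_min`` and ``y_max >= y_min``."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def to_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "BoundingBox":
        x0, y0, x1, y1 = (float(v) for v in arr)
        return cls(x0, y0, x1, y1)


@dataclass(frozen=True)
class ScoredBox:
    """A box with a classification score in [0, 1] and a category label.

    This artifact is single-class ("leaf"), so ``label`` defaults to 0 and the
    NMS below ignores it entirely.
    """

    box: BoundingBox
    score: float
    label: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


def as_box_array(boxes: Iterable) -> np.ndarray:
    """Coerce BoundingBoxes / ScoredBoxes / array-likes to an (N, 4) float array."""
    rows = []
    for b in boxes:
        if isinstance(b, ScoredBox):
            rows.append(b.box.to_array())
        elif isinstance(b, BoundingBox):
            rows.append(b.to_array())
        else:
            rows.append(np.asarray(b, dtype=float))
    if not rows:
        return np.zeros((0, 4), dtype=float)
    return np.stack(rows)


def _pairwise_intersection(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0.0, None)
    return wh[..., 0] * wh[..., 1]


def iou_matrix(a, b) -> np.ndarray:
    """Pairwise IoU between two box collections; (len(a), len(b)) array.

    A pair with zero union has IoU 0 by convention.
    """
    a = as_box_array(a)
    b = as_box_array(b)
    inter = _pairwise_intersection(a, b)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return iou


def giou_matrix(a, b) -> np.ndarray:
    """Pairwise generalized IoU: IoU - (enclosure - union) / enclosure, in (-1, 1]."""
    a = as_box_array(a)
    b = as_box_array(b)
    inter = _pairwise_intersection(a, b)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    lt = np.minimum(a[:, None, :2], b[None, :, :2])
    rb = np.maximum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0.0, None)
    enclosure = wh[..., 0] * wh[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
        g = iou - np.where(
            enclosure > 0, (enclosure - union) / np.where(enclosure > 0, enclosure, 1.0), 0.0
        )
    return g


def box_iou(a, b) -> float:
    """IoU of two boxes."""
    return float(iou_matrix([a], [b])[0, 0])


def box_giou(a, b) -> float:
    """Generalized IoU of two boxes; equals IoU when the enclosure adds no area."""
    return float(giou_matrix([a], [b])[0, 0])


def class_agnostic_nms(candidates: Sequence, iou_threshold: float = 0.7) -> list[int]:
    """Greedy score-descending suppression ignoring labels.

    Returns the kept indices into ``candidates`` in descending-score order.
    Ties on equal score are broken toward the lower original index so the
    result is deterministic. A pair of kept boxes never exceeds
    ``iou_threshold`` IoU.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold {iou_threshold} outside (0, 1]")
    cands = list(candidates)
    if not cands:
        return []
    scores = np.array(
        [c.score if isinstance(c, ScoredBox) else float(c[1]) for c in cands], dtype=float
    )
    arr = as_box_array(
        [c.box if isinstance(c, ScoredBox) else c[0] for c in cands]
    )
    # stable sort on -score keeps the lower original index first on ties
    order = np.argsort(-scores, kind="stable")
    ious = iou_matrix(arr, arr)
    kept: list[int] = []
    suppressed = np.zeros(len(cands), dtype=bool)
    for idx in order:
        if suppressed[idx]:
            continue
        kept.append(int(idx))
        suppressed |= ious[idx] > iou_threshold
    return kept


def convert_box(center_box: Sequence[float], image_width: float, image_height: float) -> BoundingBox:
    """Normalized center form (cx, cy, w, h) in [0,1] -> absolute corner form."""
    cx, cy, w, h = (float(v) for v in center_box)
    if w < 0 or h < 0:
        raise ValueError(f"negative extent in center-form box ({w}, {h})")
    return BoundingBox(
        (cx - w / 2.0) * image_width,
        (cy - h / 2.0) * image_height,
        (cx + w / 2.0) * image_width,
        (cy + h / 2.0) * image_height,
    )


def box_to_center_form(box: BoundingBox, image_width: float, image_height: float) -> np.ndarray:
    """Inverse of :func:`convert_box`: absolute corner form -> normalized (cx, cy, w, h)."""
    return np.array(
        [
            (box.x_min + box.x_max) / 2.0 / image_width,
            (box.y_min + box.y_max) / 2.0 / image_height,
            (box.x_max - box.x_min) / image_width,
            (box.y_max - box.y_min) / image_height,
        ]
    )


def xywh_to_xyxy(xywh: Sequence[float]) -> BoundingBox:
    """COCO (x, y, width, height) -> corner-form box."""
    x, y, w, h = (float(v) for v in xywh)
    return BoundingBox(x, y, x + w, y + h)


def xyxy_to_xywh(box: BoundingBox) -> list[float]:
    """Corner-form box -> COCO (x, y, width, height)."""
    return [box.x_min, box.y_min, box.width, box.height]
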