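"""Jointly trained auxiliary-head pipeline with randomized-confidence injection.

Conventional one-to-many detection heads see many positives per object, while
a set-based decoder supervises each object through a single query. This
module bridges the two: encoder memory is unflattened back into a feature
pyramid (the adapter), auxiliary heads propose boxes matched one-to-many to
ground truth, and the pooled positives are then re-scored with *random*
uniform confidences — the heads' own confidences are discarded so that easy,
high-confidence surface leaves do not monopolize the injection — suppressed
by class-agnostic NMS, and finally encoded as sinusoidal positional queries
for the decoder.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boxes import (BoundingBox, ScoredBox, box_to_center_form,
                    class_agnostic_nms, iou_matrix)
from .fpn import FeaturePyramid

__all__ = ["PositiveSample", "AuxHeadInterface", "StubHead", "flatten_pyramid",
           "adapter", "jtah_refine", "encode_as_queries", "sinusoidal_embedding"]


@dataclass(frozen=True)
class PositiveSample:
    """A positive box with its uniform-random confidence and source head index."""

    box: BoundingBox
    assigned_confidence: float
    source_head: int

    def __post_init__(self) -> None:
        if not 0.0 < self.assigned_confidence < 1.0:
            raise ValueError("assigned confidence must lie strictly in (0, 1)")


def flatten_pyramid(pyramid: FeaturePyramid) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Flatten levels into an encoder-memory array (sum(H*W), C) + level shapes.

    Tokens are ordered level-by-level, row-major within a level, channels last.
    """
    shapes = [lv.shape for lv in pyramid.levels]
    chunks = [lv.numpy().reshape(lv.shape[0], -1).T for lv in pyramid.levels]
    return np.concatenate(chunks, axis=0), shapes


def adapter(memory: np.ndarray, shapes: Sequence[tuple[int, int, int]]) -> FeaturePyramid:
    """Unflatten encoder memory back into per-level (C, H, W) grids.

    Exact inverse of :func:`flatten_pyramid`; raises on length mismatch.
    """
    memory = np.asarray(memory)
    expected = sum(h * w for _, h, w in shapes)
    if memory.shape[0] != expected:
        raise ValueError(
            f"memory has {memory.shape[0]} tokens, level shapes require {expected}"
        )
    levels = []
    offset = 0
    for c, h, w in shapes:
        n = h * w
        levels.append(memory[offset:offset + n].T.reshape(c, h, w))
        offset += n
    return FeaturePyramid(levels)


class AuxHeadInterface(ABC):
    """Contract for a pluggable auxiliary head.

    ``propose`` must return only boxes that its own (one-to-many) assignment
    rule accepts against some ground truth; several proposals may cover the
    same ground truth.
    """

    @abstractmethod
    def propose(self, features: FeaturePyramid,
                ground_truths: Sequence[BoundingBox],
                image_size: tuple[float, float],
                rng: np.random.Generator) -> list[BoundingBox]:
        ...


class StubHead(AuxHeadInterface):
    """Desk-scale stand-in for a conventional dense detection head.

    Reads activation peaks from the finest pyramid level, proposes jittered
    anchors around them (anchor extents drawn around the median ground-truth
    size), and keeps every proposal whose IoU with *some* ground truth reaches
    ``iou_accept`` — a one-to-many rule by construction.
    """

    def __init__(self, iou_accept: float = 0.5, peaks: int = 32,
                 proposals_per_peak: int = 3, jitter: float = 0.25):
        self.iou_accept = iou_accept
        self.peaks = peaks
        self.proposals_per_peak = proposals_per_peak
        self.jitter = jitter

    def propose(self, features: FeaturePyramid,
                ground_truths: Sequence[BoundingBox],
                image_size: tuple[float, float],
                rng: np.random.Generator) -> list[BoundingBox]:
        if not ground_truths:
            return []
        img_w, img_h = image_size
        act = features[0].numpy().mean(axis=0)  # (H, W) activation energy
        h, w = act.shape
        stride_y, stride_x = img_h / h, img_w / w
        flat = np.argsort(act, axis=None)[::-1][: self.peaks]
        rows, cols = np.unravel_index(flat, act.shape)
        med_w = float(np.median([g.width for g in ground_truths]))
        med_h = float(np.median([g.height for g in ground_truths]))
        proposals: list[BoundingBox] = []
        for r, c in zip(rows, cols):
            cy = (r + 0.5) * stride_y
            cx = (c + 0.5) * stride_x
            for _ in range(self.proposals_per_peak):
                jw = med_w * (1 + self.jitter * rng.uniform(-1, 1))
                jh = med_h * (1 + self.jitter * rng.uniform(-1, 1))
                jx = cx + self.jitter * med_w * rng.uniform(-1, 1)
                jy = cy + self.jitter * med_h * rng.uniform(-1, 1)
                proposals.append(BoundingBox(
                    max(jx - jw / 2, 0.0), max(jy - jh / 2, 0.0),
                    min(jx + jw / 2, img_w), min(jy + jh / 2, img_h),
                ))
        if not proposals:
            return []
        ious = iou_matrix(proposals, ground_truths)
        keep = ious.max(axis=1) >= self.iou_accept
        return [p for p, k in zip(proposals, keep) if k]


def jtah_refine(pos_lists: Sequence[Sequence[BoundingBox]],
                seed: int | np.random.Generator,
                nms_threshold: float = 0.7) -> list[PositiveSample]:
    """Pool head positives, assign U(0, 1) confidences, suppress overlaps.

    Confidences are drawn i.i.d. from the open unit interval with the given
    seed; which of two mutually overlapping positives survives is therefore a
    coin flip rather than a function of any head's confidence. Deterministic
    for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled: list[tuple[BoundingBox, int]] = []
    for head_idx, positives in enumerate(pos_lists):
        pooled.extend((box, head_idx) for box in positives)
    if not pooled:
        return []
    conf = rng.uniform(0.0, 1.0, size=len(pooled))
    # keep confidences strictly inside (0, 1)
    conf = np.clip(conf, 1e-12, 1 - 1e-12)
    scored = [ScoredBox(box, float(s)) for (box, _), s in zip(pooled, conf)]
    kept = class_agnostic_nms(scored, nms_threshold)
    return [PositiveSample(pooled[i][0], float(conf[i]), pooled[i][1]) for i in kept]


def sinusoidal_embedding(values: np.ndarray, dim: int, temperature: float = 10000.0) -> np.ndarray:
    """Fixed sin/cos embedding of (N, 4) normalized box coordinates to (N, dim).

    Each coordinate receives ``dim // 4`` features: interleaved sine and
    cosine at geometrically spaced frequencies, the DETR positional-encoding
    convention.
    """
    if dim % 8:
        raise ValueError("embedding dimension must be a multiple of 8")
    per_coord = dim // 4
    freq_idx = np.arange(per_coord // 2)
    inv_freq = 1.0 / temperature ** (2 * freq_idx / per_coord)
    angles = 2 * np.pi * values[:, :, None] * inv_freq[None, None, :]  # (N, 4, per/2)
    emb = np.concatenate([np.sin(angles), np.cos(angles)], axis=-1)    # (N, 4, per)
    return emb.reshape(values.shape[0], dim)


def encode_as_queries(samples: Sequence[PositiveSample], dim: int,
                      image_size: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Map positive samples to decoder query embeddings + reference boxes.

    Returns ``(embeddings (N, dim), references (N, 4))`` with references in
    normalized center form; identical boxes produce identical embeddings.
    """
    if not samples:
        return np.zeros((0, dim)), np.zeros((0, 4))
    w, h = image_size
    refs = np.stack([box_to_center_form(s.box, w, h) for s in samples])
    return sinusoidal_embedding(refs, dim), refs
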