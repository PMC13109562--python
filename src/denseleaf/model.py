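"""Miniature end-to-end set-based detector exercising the dense-leaf modules.

The novelty under test lives in the progressive pyramid, the crowded-query
matching and the randomized auxiliary-head injection; the surrounding network
is deliberately minimal so everything runs on a CPU in seconds: a three-stage
strided convolutional backbone, a flatten-plus-linear encoder stand-in, and a
single-head cross-attention decoder emitting one normalized center-form box
and one foreground logit per query.

Training mode differs from eval mode exactly as the training strategy
prescribes: the extra query branch and the auxiliary-head injection exist
only while training; inference uses the original queries alone, with no NMS
by default (end-to-end convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .assign import Assignment, MatchConfig, cqr_compose, combined_loss
from .aux_head import StubHead, encode_as_queries, flatten_pyramid, jtah_refine
from .boxes import BoundingBox, ScoredBox, class_agnostic_nms, convert_box
from .fpn import FeaturePyramid, ProgressiveFPN
from .nn import Conv2d, Linear, Module, Parameter

__all__ = ["ModelConfig", "MiniDetector", "build_model", "DetectionOutput"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and ablation switches of the miniature detector.

    ``num_extra_queries`` defaults to the original query count when None.
    The three toggles (`use_fpn`, `use_cqr`, `use_aux`) are independent so
    every ablation arm of the method can be exercised.
    """

    channels: int = 32
    num_levels: int = 3
    num_queries: int = 300
    num_extra_queries: int | None = None
    decoder_layers: int = 1
    match: MatchConfig = field(default_factory=MatchConfig)
    use_fpn: bool = True
    use_cqr: bool = True
    use_aux: bool = True
    upsample: str = "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_queries < 1:
            raise ValueError("need at least one query")
        if self.channels % 8:
            raise ValueError("channels must be a multiple of 8 (sinusoidal encoding)")

    @property
    def extra_queries(self) -> int:
        return self.num_queries if self.num_extra_queries is None else self.num_extra_queries


@dataclass
class DetectionOutput:
    """Raw per-query decoder outputs for one branch (normalized boxes)."""

    boxes: Tensor   # (N, 4) center form in [0, 1]
    logits: Tensor  # (N,)

    def scored_boxes(self, image_size: tuple[float, float]) -> list[ScoredBox]:
        w, h = image_size
        probs = 1.0 / (1.0 + np.exp(-self.logits.numpy()))
        out = []
        for b, p in zip(self.boxes.numpy(), probs):
            out.append(ScoredBox(convert_box(b, w, h), float(p)))
        return out


def _column(x: Tensor, i: int) -> Tensor:
    """Differentiable extraction of column i of an (N, 4) tensor as (N, 1)."""
    e = Tensor(np.eye(x.shape[1])[:, [i]])
    return x @ e


def _gather_rows(x: Tensor, rows: Sequence[int]) -> Tensor:
    """Differentiable row gather via a selection matmul."""
    sel = np.zeros((len(rows), x.shape[0]))
    sel[np.arange(len(rows)), list(rows)] = 1.0
    return Tensor(sel) @ x


def giou_loss_terms(pred_center: Tensor, gt_center: np.ndarray) -> Tensor:
    """Per-pair (1 - GIoU) for matched normalized center-form boxes; (M, 1)."""
    eps = 1e-9
    cx, cy, w, h = (_column(pred_center, i) for i in range(4))
    px0, py0 = cx - w * 0.5, cy - h * 0.5
    px1, py1 = cx + w * 0.5, cy + h * 0.5
    g = np.asarray(gt_center, dtype=float)
    gx0, gy0 = g[:, [0]] - g[:, [2]] / 2, g[:, [1]] - g[:, [3]] / 2
    gx1, gy1 = g[:, [0]] + g[:, [2]] / 2, g[:, [1]] + g[:, [3]] / 2
    iw = ad.relu(ad.minimum(px1, gx1) - ad.maximum(px0, gx0))
    ih = ad.relu(ad.minimum(py1, gy1) - ad.maximum(py0, gy0))
    inter = iw * ih
    area_p = w * h
    area_g = (gx1 - gx0) * (gy1 - gy0)
    union = area_p + area_g - inter
    iou = inter / (union + eps)
    ew = ad.maximum(px1, gx1) - ad.minimum(px0, gx0)
    eh = ad.maximum(py1, gy1) - ad.minimum(py0, gy0)
    enclosure = ew * eh
    giou = iou - (enclosure - union) / (enclosure + eps)
    return 1.0 - giou


def focal_loss(logits: Tensor, targets: np.ndarray,
               alpha: float = 0.25, gamma: float = 2.0) -> Tensor:
    """Mean sigmoid focal loss over one branch's query logits."""
    t = np.asarray(targets, dtype=float)
    p = ad.sigmoid(logits)
    eps = 1e-12
    pos = Tensor(t) * (1.0 - p) ** gamma * ad.log(p + eps) * (-alpha)
    neg = Tensor(1.0 - t) * p ** gamma * ad.log(1.0 - p + eps) * (-(1.0 - alpha))
    return (pos + neg).mean()


class DecoderLayer(Module):
    """Single-head cross-attention + position-wise feed-forward, residual."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.ff1 = Linear(dim, dim, rng)
        self.ff2 = Linear(dim, dim, rng)
        self.scale = 1.0 / np.sqrt(dim)

    def __call__(self, queries: Tensor, memory: Tensor) -> Tensor:
        attn = ad.softmax_lastdim((self.wq(queries) @ self.wk(memory).T) * self.scale)
        x = queries + self.wo(attn @ self.wv(memory))
        return x + self.ff2(ad.relu(self.ff1(x)))


class MiniDetector(Module):
    """Backbone -> (progressive) pyramid -> encoder memory -> query decoder."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        c = config.channels
        self.config = config
        # strided stages: strides 4, 8, 16, ... relative to the input
        self.stem = Conv2d(3, c, 3, rng, stride=2, padding=1)
        self.stages = [Conv2d(c, c, 3, rng, stride=2, padding=1)
                       for _ in range(config.num_levels)]
        self.fpn = ProgressiveFPN(c, config.num_levels, rng, config.upsample)
        self.enc = Linear(c, c, rng)
        self.decoder = [DecoderLayer(c, rng) for _ in range(config.decoder_layers)]
        self.query_embed = Parameter(rng.normal(0, 0.5, (config.num_queries, c)))
        self.extra_embed = Parameter(rng.normal(0, 0.5, (config.extra_queries, c)))
        self.cls_head = Linear(c, 1, rng)
        # rare-foreground prior on the classification bias
        self.cls_head.bias.data[:] = -2.0
        box_hidden = Linear(c, c, rng)
        box_out = Linear(c, 4, rng)
        self.box_hidden = box_hidden
        self.box_out = box_out
        self.aux_head = StubHead()
        self.training = True

    # -- mode -------------------------------------------------------------
    def train_mode(self) -> None:
        self.training = True

    def eval_mode(self) -> None:
        self.training = False

    # -- forward pieces ----------------------------------------------------
    def backbone(self, image: np.ndarray) -> FeaturePyramid:
        x = Tensor(np.asarray(image, dtype=np.float64) / 255.0)
        x = ad.relu(self.stem(x))
        levels = []
        for stage in self.stages:
            x = ad.relu(stage(x))
            levels.append(x)
        return FeaturePyramid(levels)

    def features(self, image: np.ndarray) -> FeaturePyramid:
        pyramid = self.backbone(image)
        if self.config.use_fpn:
            return self.fpn(pyramid)
        return pyramid  # identity fusion keeps shapes unchanged

    def encode(self, pyramid: FeaturePyramid) -> Tensor:
        chunks = []
        for lv in pyramid.levels:
            c, h, w = lv.shape
            chunks.append(lv.reshape(c, h * w).T)
        memory = ad.concat(chunks, axis=0)
        return memory + ad.relu(self.enc(memory))

    def decode(self, query_embeddings: Tensor, memory: Tensor) -> DetectionOutput:
        x = query_embeddings
        for layer in self.decoder:
            x = layer(x, memory)
        logits = self.cls_head(x).reshape(-1)
        boxes = ad.sigmoid(self.box_out(ad.relu(self.box_hidden(x))))
        return DetectionOutput(boxes, logits)

    # -- public API ---------------------------------------------------------
    def forward(self, image: np.ndarray,
                ground_truths: Sequence[BoundingBox] | None = None,
                aux_rng: np.random.Generator | None = None,
                ) -> dict:
        """Run the detector on one (3, H, W) image.

        In eval mode only the original branch runs. In training mode the
        extra branch (when CQR is on) and the auxiliary-head injected queries
        (when the aux head is on and ground truths are given) are decoded as
        well; injected queries join the extra pool for one-to-many
        supervision.
        """
        _, ih, iw = image.shape
        pyramid = self.features(image)
        memory = self.encode(pyramid)
        out: dict = {"image_size": (float(iw), float(ih))}
        out["original"] = self.decode(self.query_embed, memory)
        if not (self.training and self.config.use_cqr):
            out["extra"] = None
            out["num_injected"] = 0
            return out

        extra_embed: Tensor = self.extra_embed
        num_injected = 0
        if self.config.use_aux and ground_truths:
            rng = aux_rng if aux_rng is not None else np.random.default_rng(self.config.seed)
            detached = FeaturePyramid([lv.detach() for lv in pyramid.levels])
            positives = self.aux_head.propose(detached, ground_truths,
                                              (float(iw), float(ih)), rng)
            samples = jtah_refine([positives], rng, self.config.match.nms_threshold)
            emb, _ = encode_as_queries(samples, self.config.channels, (float(iw), float(ih)))
            num_injected = emb.shape[0]
            if num_injected:
                extra_embed = ad.concat([extra_embed, Tensor(emb)], axis=0)
        out["extra"] = self.decode(extra_embed, memory)
        out["num_injected"] = num_injected
        return out

    def loss(self, image: np.ndarray, ground_truths: Sequence[BoundingBox],
             aux_rng: np.random.Generator | None = None) -> tuple[Tensor, dict]:
        """Dual-branch training loss for one image + matching statistics."""
        fwd = self.forward(image, ground_truths, aux_rng)
        image_size = fwd["image_size"]
        match_cfg = self.config.match
        if not self.config.use_cqr:
            # plain one-to-one baseline: no culling, no extra branch
            match_cfg = replace(match_cfg, nms_threshold=1.0)

        ori: DetectionOutput = fwd["original"]
        extra: DetectionOutput | None = fwd["extra"]
        ori_scored = ori.scored_boxes(image_size)
        extra_scored = extra.scored_boxes(image_size) if extra is not None else []
        assign_ori, assign_extra = cqr_compose(ori_scored, extra_scored,
                                               list(ground_truths), match_cfg,
                                               image_size)
        gt_center = np.stack(
            [np.array([(g.x_min + g.x_max) / 2 / image_size[0],
                       (g.y_min + g.y_max) / 2 / image_size[1],
                       g.width / image_size[0], g.height / image_size[1]])
             for g in ground_truths]) if ground_truths else np.zeros((0, 4))

        loss_ori = self._branch_loss(ori, assign_ori, gt_center)
        loss_extra = (self._branch_loss(extra, assign_extra, gt_center)
                      if extra is not None else Tensor(0.0))
        weight = self.config.match.extra_loss_weight if extra is not None else 0.0
        total = loss_ori + weight * loss_extra
        stats = {
            "assign_ori": assign_ori,
            "assign_extra": assign_extra,
            "num_injected": fwd["num_injected"],
            "loss_ori": float(loss_ori.numpy()),
            "loss_extra": float(loss_extra.numpy()),
            "combined": combined_loss(float(loss_ori.numpy()),
                                      float(loss_extra.numpy()), weight),
        }
        return total, stats

    def _branch_loss(self, branch: DetectionOutput, assignment: Assignment,
                     gt_center: np.ndarray,
                     w_l1: float = 5.0, w_giou: float = 2.0) -> Tensor:
        n = branch.logits.shape[0]
        targets = np.zeros(n)
        for p, _ in assignment.pairs:
            targets[p] = 1.0
        cls = focal_loss(branch.logits, targets)
        if not assignment.pairs:
            return cls
        rows = [p for p, _ in assignment.pairs]
        gts = gt_center[[g for _, g in assignment.pairs]]
        pred = _gather_rows(branch.boxes, rows)
        l1 = ad.absolute(pred - Tensor(gts)).sum(axis=1).mean()
        giou = giou_loss_terms(pred, gts).mean()
        return cls + w_l1 * l1 + w_giou * giou

    def infer(self, image: np.ndarray, score_threshold: float = 0.5,
              nms_at_inference: bool = False,
              nms_threshold: float | None = None) -> list[ScoredBox]:
        """End-to-end inference: original queries only, thresholded by score.

        No NMS by default; the optional flag applies class-agnostic NMS with
        the matcher's threshold (or an explicit one).
        """
        was_training = self.training
        self.eval_mode()
        try:
            fwd = self.forward(image)
        finally:
            self.training = was_training
        dets = [d for d in fwd["original"].scored_boxes(fwd["image_size"])
                if d.score >= score_threshold]
        if nms_at_inference and dets:
            thr = nms_threshold if nms_threshold is not None else self.config.match.nms_threshold
            dets = [dets[i] for i in class_agnostic_nms(dets, thr)]
        return dets


def build_model(config: ModelConfig) -> MiniDetector:
    """Construct the miniature detector from its configuration."""
    return MiniDetector(config)
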