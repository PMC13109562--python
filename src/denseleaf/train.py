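"""Seeded training loop, evaluation and the smoke-training contract.

Optimization follows the usual set-based detector recipe: AdamW-style Adam
(learning rate 2e-4, weight decay 1e-4), gradient clipping by global L2 norm
at 0.1, a 12-epoch schedule with a single 10x learning-rate drop at epoch 11,
and an 8:2 train/validation split. The desk-scale smoke run iterates a fixed
number of steps (one image per step, cycling through the training scenes) and
reports the loss trajectory plus a validation metric summary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .metrics import APSummary, summarize
from .model import MiniDetector
from .nn import Adam, clip_grad_norm
from .scenes import Scene, annotate_scene

__all__ = ["TrainConfig", "TrainResult", "train_smoke", "evaluate", "split_scenes"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    weight_decay: float = 1e-4
    grad_clip_norm: float = 0.1
    epochs: int = 12
    lr_step_epoch: int = 11
    batch_size: int = 2
    seed: int = 0
    train_split: float = 0.8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if not 0.0 < self.train_split < 1.0:
            raise ValueError("train_split must lie in (0, 1)")


@dataclass
class TrainResult:
    losses: list[float]
    summary: APSummary | None
    stats: list[dict] = field(default_factory=list)

    def decile_means(self) -> tuple[float, float]:
        """Mean loss over the first and the final 10% of iterations."""
        n = max(len(self.losses) // 10, 1)
        return float(np.mean(self.losses[:n])), float(np.mean(self.losses[-n:]))

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "loss"])
            for i, v in enumerate(self.losses):
                writer.writerow([i, f"{v:.6f}"])


def split_scenes(scenes: Sequence[Scene], train_split: float,
                 seed: int) -> tuple[list[Scene], list[Scene]]:
    """Deterministic shuffled train/validation split."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scenes))
    cut = max(int(round(len(scenes) * train_split)), 1)
    return ([scenes[i] for i in order[:cut]],
            [scenes[i] for i in order[cut:]])


def train_smoke(scenes: Sequence[Scene], model: MiniDetector, config: TrainConfig,
                iterations: int = 200, log_csv: str | Path | None = None,
                evaluate_after: bool = True) -> TrainResult:
    """Short seeded optimization run over synthetic scenes.

    One training image per step, cycling through the training split; the
    learning rate drops 10x at the configured epoch fraction of the run.
    Raises ``FloatingPointError`` on divergence (non-finite loss). For a fixed
    seed the loss trajectory is bit-reproducible.
    """
    if len(scenes) < 2:
        raise ValueError("need at least two scenes to split")
    train_set, val_set = split_scenes(scenes, config.train_split, config.seed)
    model.train_mode()
    params = list(model.parameters())
    opt = Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    aux_rng = np.random.default_rng(config.seed + 1)
    step_at = int(iterations * config.lr_step_epoch / config.epochs)

    losses: list[float] = []
    stats_log: list[dict] = []
    for it in range(iterations):
        if it == step_at:
            opt.lr = config.learning_rate * 0.1
        scene = train_set[it % len(train_set)]
        gts = annotate_scene(scene.instances, scene.spec.min_visible_fraction)
        image = np.moveaxis(scene.image, -1, 0)
        loss, stats = model.loss(image, gts, aux_rng)
        value = float(loss.numpy())
        if not np.isfinite(value):
            raise FloatingPointError(f"training diverged at iteration {it}")
        opt.zero_grad()
        loss.backward()
        clip_grad_norm(params, config.grad_clip_norm)
        opt.step()
        losses.append(value)
        stats_log.append(stats)

    result = TrainResult(losses, None, stats_log)
    if log_csv is not None:
        result.write_csv(log_csv)
    if evaluate_after and val_set:
        result.summary = evaluate(val_set, model)
    return result


def evaluate(scenes: Sequence[Scene], model: MiniDetector,
             score_threshold: float = 0.05) -> APSummary:
    """Run inference over scenes and score against their annotations."""
    dets = {}
    gts = {}
    for idx, scene in enumerate(scenes, start=1):
        gts[idx] = annotate_scene(scene.instances, scene.spec.min_visible_fraction)
        image = np.moveaxis(scene.image, -1, 0)
        dets[idx] = model.infer(image, score_threshold=score_threshold)
    return summarize(dets, gts)
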