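"""Progressive feature-pyramid fusion with adaptive feature aggregation.

The pyramid is fused strictly top-down. The coarsest level is first passed
through a feed-forward transform (position-wise linear, 3x3 convolution,
position-wise linear). Every finer level is then combined with the 2x-upsampled
result of the level above it by the Adaptive Feature Aggregation (AFA)
operator, so each output level depends on all levels above it. AFA is a
dual-path gate:

* a **spatial gate** — each input is compressed to one channel by a 1x1
  convolution, the two maps are added and squashed by a sigmoid, giving a
  single-channel attention map over locations;
* a **channel gate** — the inputs are concatenated to 2C channels, globally
  average-pooled, mapped through a linear layer and a sigmoid to per-channel
  weights in (0, 1), multiplied back onto the concatenated map, and reduced
  to C channels by a 1x1 convolution.

The fused output is the elementwise product of the channel-gated map and the
broadcast spatial gate. The gating sharpens leaf-edge evidence where densely
overlapping, similarly textured objects would otherwise blur together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, concat, resample_nearest, sigmoid
from .nn import Conv2d, Linear, Module

__all__ = ["FeaturePyramid", "TopTransform", "AdaptiveFeatureAggregation",
           "ProgressiveFPN", "resample_bilinear"]


@dataclass
class FeaturePyramid:
    """Ordered feature maps, index 0 = highest resolution, uniform channels.

    Consecutive levels must halve spatially (floor or ceil, accommodating odd
    sizes from strided convolutions).
    """

    levels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.levels = [lv if isinstance(lv, Tensor) else Tensor(lv) for lv in self.levels]
        if not self.levels:
            raise ValueError("pyramid needs at least one level")
        c0 = self.levels[0].shape[0]
        for i, lv in enumerate(self.levels):
            if lv.ndim != 3:
                raise ValueError(f"level {i} is not a (C, H, W) map")
            if lv.shape[0] != c0:
                raise ValueError(f"level {i} has {lv.shape[0]} channels, expected {c0}")
        for i in range(len(self.levels) - 1):
            _, h, w = self.levels[i].shape
            _, h2, w2 = self.levels[i + 1].shape
            if h2 not in (h // 2, (h + 1) // 2) or w2 not in (w // 2, (w + 1) // 2):
                raise ValueError(
                    f"level {i + 1} shape {(h2, w2)} does not halve level {i} shape {(h, w)}"
                )

    @property
    def channels(self) -> int:
        return self.levels[0].shape[0]

    @property
    def shapes(self) -> list[tuple[int, int, int]]:
        return [lv.shape for lv in self.levels]

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, i: int) -> Tensor:
        return self.levels[i]


def resample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resampling as two fixed interpolation matmuls (differentiable)."""

    def interp_matrix(n_out: int, n_in: int) -> np.ndarray:
        m = np.zeros((n_out, n_in))
        if n_in == 1:
            m[:, 0] = 1.0
            return m
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = src - lo
        m[np.arange(n_out), lo] += 1 - frac
        m[np.arange(n_out), hi] += frac
        return m

    c, h, w = x.shape
    col = Tensor(interp_matrix(out_w, w).T)  # (w, out_w)
    row = Tensor(interp_matrix(out_h, h).T)  # (h, out_h)
    y = (x.reshape(c * h, w) @ col).reshape(c, h, out_w)
    y = (y.transpose(0, 2, 1).reshape(c * out_w, h) @ row).reshape(c, out_w, out_h)
    return y.transpose(0, 2, 1)


class TopTransform(Module):
    """Feed-forward transform for the coarsest level: 1x1 -> 3x3 -> 1x1."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.fc_in = Conv2d(channels, channels, 1, rng)
        self.conv = Conv2d(channels, channels, 3, rng, padding=1)
        self.fc_out = Conv2d(channels, channels, 1, rng)
        self.channels = channels

    def __call__(self, level_latest: Tensor) -> Tensor:
        if level_latest.shape[0] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {level_latest.shape[0]}"
            )
        return self.fc_out(self.conv(self.fc_in(level_latest)))


class AdaptiveFeatureAggregation(Module):
    """Dual-path spatial x channel gating of two same-shape feature maps."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.squeeze1 = Conv2d(channels, 1, 1, rng)
        self.squeeze2 = Conv2d(channels, 1, 1, rng)
        self.excite = Linear(2 * channels, 2 * channels, rng)
        self.reduce = Conv2d(2 * channels, channels, 1, rng)

    def _check(self, p1: Tensor, p2: Tensor) -> None:
        if p1.shape != p2.shape:
            raise ValueError(f"AFA inputs differ in shape: {p1.shape} vs {p2.shape}")
        if p1.shape[0] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {p1.shape[0]}")

    def spatial_gate(self, p1: Tensor, p2: Tensor) -> Tensor:
        """Single-channel (1, H, W) attention map, values strictly in (0, 1)."""
        self._check(p1, p2)
        return sigmoid(self.squeeze1(p1) + self.squeeze2(p2))

    def channel_weights(self, p12: Tensor) -> Tensor:
        """Per-channel weights of length 2C from the pooled concatenated map."""
        pooled = p12.mean(axis=(1, 2))  # (2C,)
        return sigmoid(self.excite(pooled.reshape(1, -1)).reshape(-1))

    def channel_gate(self, p1: Tensor, p2: Tensor) -> Tensor:
        """(C, H, W) map: concatenation re-weighted per channel, then reduced."""
        self._check(p1, p2)
        p12 = concat([p1, p2], axis=0)
        w = self.channel_weights(p12)
        return self.reduce(p12 * w.reshape(-1, 1, 1))

    def __call__(self, p1: Tensor, p2: Tensor) -> Tensor:
        return self.channel_gate(p1, p2) * self.spatial_gate(p1, p2)


class ProgressiveFPN(Module):
    """Top-down progressive fusion over a channel-uniform pyramid.

    Parameters
    ----------
    channels : feature width shared by every pyramid level.
    num_levels : number of pyramid levels the network fuses.
    rng : seeded generator for weight initialization.
    upsample : "nearest" (default) or "bilinear". Odd-size mismatches are
        handled by resampling the coarser map to the finer level's exact
        height and width.
    """

    def __init__(self, channels: int, num_levels: int, rng: np.random.Generator,
                 upsample: str = "nearest"):
        if num_levels < 1:
            raise ValueError("need at least one level")
        if upsample not in ("nearest", "bilinear"):
            raise ValueError(f"unknown upsample mode {upsample!r}")
        self.channels = channels
        self.num_levels = num_levels
        self.upsample = upsample
        self.top = TopTransform(channels, rng)
        self.afas = [AdaptiveFeatureAggregation(channels, rng) for _ in range(num_levels - 1)]

    def _upsample_to(self, x: Tensor, h: int, w: int) -> Tensor:
        if self.upsample == "nearest":
            return resample_nearest(x, h, w)
        return resample_bilinear(x, h, w)

    def __call__(self, pyramid: FeaturePyramid) -> FeaturePyramid:
        if len(pyramid) != self.num_levels:
            raise ValueError(f"expected {self.num_levels} levels, got {len(pyramid)}")
        if pyramid.channels != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {pyramid.channels}")
        out: list[Tensor] = [None] * len(pyramid)  # type: ignore[list-item]
        out[-1] = self.top(pyramid[len(pyramid) - 1])
        for i in range(len(pyramid) - 2, -1, -1):
            _, h, w = pyramid[i].shape
            up = self._upsample_to(out[i + 1], h, w)
            out[i] = self.afas[i](pyramid[i], up)
        return FeaturePyramid(out)
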