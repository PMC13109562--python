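"""Dataset-construction computations for aerial canopy imagery.

Large source frames are cut into fixed windows by a sliding-window pass
(defaults: a 9504x6336 window moved with a 5000-pixel step), annotations are
clipped and translated into window coordinates, count-based screening drops
sparse tiles, and density statistics summarize the result as boxes per image
truncated to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Sequence

from .boxes import BoundingBox

__all__ = ["TileSpec", "DatasetStats", "sliding_windows", "crop_boxes",
           "screen_tile", "density_stats", "tile_dataset"]

# area fraction a clipped box must retain to survive the crop; reuses the
# 1/3 visible-fraction annotation convention
CROP_KEEP_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class TileSpec:
    """Sliding-window geometry; defaults match the full sensor frame."""

    window_width: int = 9504
    window_height: int = 6336
    step: int = 5000
    clamp_to_edge: bool = True

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.window_width <= 0 or self.window_height <= 0:
            raise ValueError("window dimensions must be positive")


@dataclass(frozen=True)
class DatasetStats:
    """Image/annotation counts and boxes-per-image density (truncated)."""

    images: int
    boxes: int
    density: float


def _axis_origins(source: int, window: int, step: int, clamp: bool) -> list[int]:
    if window >= source:
        return [0]
    origins = list(range(0, source - window + 1, step))
    if clamp and origins[-1] + window < source:
        origins.append(source - window)
    return origins


def sliding_windows(source_w: int, source_h: int, spec: TileSpec) -> list[tuple[int, int]]:
    """Window origins (x, y) in row-major order.

    Origins advance by ``spec.step`` per axis while the window fits; when the
    last full step leaves uncovered pixels and clamping is on, one final
    origin is clamped to ``source - window``. A window larger than the source
    yields the single origin (0, 0) (the window is cropped to the source when
    the tile is extracted).
    """
    if source_w <= 0 or source_h <= 0:
        raise ValueError("source dimensions must be positive")
    xs = _axis_origins(source_w, spec.window_width, spec.step, spec.clamp_to_edge)
    ys = _axis_origins(source_h, spec.window_height, spec.step, spec.clamp_to_edge)
    return [(x, y) for y in ys for x in xs]


def crop_boxes(boxes: Sequence[BoundingBox], window: BoundingBox,
               keep_fraction: float = CROP_KEEP_FRACTION) -> list[BoundingBox]:
    """Clip boxes to a window and translate them into window coordinates.

    A box survives only if at least ``keep_fraction`` of its original area
    remains after clipping; boxes outside the window are dropped.
    """
    kept = []
    for box in boxes:
        x0 = max(box.x_min, window.x_min)
        y0 = max(box.y_min, window.y_min)
        x1 = min(box.x_max, window.x_max)
        y1 = min(box.y_max, window.y_max)
        if x1 <= x0 or y1 <= y0:
            continue
        clipped_area = (x1 - x0) * (y1 - y0)
        if box.area > 0 and clipped_area / box.area < keep_fraction:
            continue
        kept.append(BoundingBox(x0 - window.x_min, y0 - window.y_min,
                                x1 - window.x_min, y1 - window.y_min))
    return kept


def screen_tile(annotation_count: int, min_boxes: int = 50) -> bool:
    """Count-based screening: keep a tile iff it holds at least ``min_boxes``.

    The same predicate with ``min_boxes=200`` screens whole source images
    before tiling (sparse-canopy rejection).
    """
    if annotation_count < 0:
        raise ValueError("annotation count must be >= 0")
    return annotation_count >= min_boxes


def density_stats(image_count: int, box_count: int) -> DatasetStats:
    """Boxes-per-image density, truncated (not rounded) to two decimals."""
    if image_count <= 0:
        raise ValueError("image count must be positive")
    density = floor(box_count / image_count * 100) / 100.0
    return DatasetStats(image_count, box_count, density)


def tile_dataset(source_w: int, source_h: int, boxes: Sequence[BoundingBox],
                 spec: TileSpec | None = None, min_boxes: int = 50,
                 ) -> list[tuple[BoundingBox, list[BoundingBox]]]:
    """Full pipeline: windows -> per-window clipped boxes -> count screening.

    Returns the surviving (window, boxes-in-window-coordinates) pairs.
    """
    spec = spec or TileSpec()
    tiles = []
    for x, y in sliding_windows(source_w, source_h, spec):
        window = BoundingBox(x, y, min(x + spec.window_width, source_w),
                             min(y + spec.window_height, source_h))
        inside = crop_boxes(boxes, window)
        if screen_tile(len(inside), min_boxes):
            tiles.append((window, inside))
    return tiles
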