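"""COCO detection JSON reading and writing.

Ground truth uses the standard dictionary layout (``images``, ``annotations``
with xywh boxes / ``area`` / ``iscrowd``, ``categories``); detection results
use the flat result-list layout (``image_id``, ``bbox``, ``score``,
``category_id``). The single category here is "leaf".
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from .boxes import BoundingBox, ScoredBox, xywh_to_xyxy, xyxy_to_xywh

__all__ = ["LEAF_CATEGORY_ID", "write_ground_truth", "read_ground_truth",
           "write_detections", "read_detections"]

LEAF_CATEGORY_ID = 1


def write_ground_truth(gts_per_image: Mapping, path,
                       image_sizes: Mapping | None = None) -> None:
    """Write per-image ground-truth boxes to a COCO detection JSON file.

    ``image_sizes`` optionally maps image id -> (width, height); unspecified
    sizes are omitted from the image records.
    """
    images, annotations = [], []
    ann_id = 1
    for img_id in sorted(gts_per_image):
        rec = {"id": int(img_id), "file_name": f"{img_id}.png"}
        if image_sizes and img_id in image_sizes:
            rec["width"], rec["height"] = (int(v) for v in image_sizes[img_id])
        images.append(rec)
        for box in gts_per_image[img_id]:
            annotations.append({
                "id": ann_id,
                "image_id": int(img_id),
                "category_id": LEAF_CATEGORY_ID,
                "bbox": [float(v) for v in xyxy_to_xywh(box)],
                "area": float(box.area),
                "iscrowd": 0,
            })
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": LEAF_CATEGORY_ID, "name": "leaf"}],
    }
    Path(path).write_text(json.dumps(doc))


def read_ground_truth(path) -> dict[int, list[BoundingBox]]:
    """Read a COCO ground-truth file into image id -> list of corner-form boxes."""
    doc = json.loads(Path(path).read_text())
    gts: dict[int, list[BoundingBox]] = {int(img["id"]): [] for img in doc["images"]}
    for ann in doc["annotations"]:
        gts[int(ann["image_id"])].append(xywh_to_xyxy(ann["bbox"]))
    return gts


def write_detections(dets_per_image: Mapping, path) -> None:
    """Write per-image scored boxes as a COCO result list."""
    results = []
    for img_id in sorted(dets_per_image):
        for det in dets_per_image[img_id]:
            results.append({
                "image_id": int(img_id),
                "category_id": LEAF_CATEGORY_ID,
                "bbox": [float(v) for v in xyxy_to_xywh(det.box)],
                "score": float(det.score),
            })
    Path(path).write_text(json.dumps(results))


def read_detections(path) -> dict[int, list[ScoredBox]]:
    """Read a COCO result list into image id -> list of ScoredBox."""
    results = json.loads(Path(path).read_text())
    dets: dict[int, list[ScoredBox]] = {}
    for rec in results:
        dets.setdefault(int(rec["image_id"]), []).append(
            ScoredBox(xywh_to_xyxy(rec["bbox"]), float(rec["score"]))
        )
    return dets
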