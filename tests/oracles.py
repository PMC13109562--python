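"""Independent oracle implementations used only by the test suite.

Each oracle recomputes a quantity along a different code path from the
package (loops instead of vectorization, enumeration instead of
optimization, the COCO accumulation algorithm instead of the package's
envelope sampling) so agreement is evidence of correctness rather than
repetition.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def iou_scalar(a, b) -> float:
    """Straight-line IoU of two (x0, y0, x1, y1) boxes."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(ix1 - ix0, 0.0) * max(iy1 - iy0, 0.0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def nms_oracle(boxes: np.ndarray, scores: np.ndarray, threshold: float) -> list[int]:
    """Brute-force greedy suppression: repeatedly take the best remaining box."""
    remaining = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [i for i in remaining
                     if iou_scalar(boxes[best], boxes[i]) <= threshold]
    return kept


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def hungarian_oracle(cost: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Minimum-cost one-to-one assignment by exhaustive enumeration.

    Enumerates every injective map from the smaller side into the larger one
    (the smaller side is always fully assigned in an optimal solution).
    """
    P, G = cost.shape
    if P == 0 or G == 0:
        return [], 0.0
    best_total = np.inf
    best_pairs: list[tuple[int, int]] = []
    if P <= G:
        for cols in itertools.permutations(range(G), P):
            total = sum(cost[r, c] for r, c in enumerate(cols))
            if total < best_total - 1e-15:
                best_total = total
                best_pairs = sorted(enumerate(cols))
    else:
        for rows in itertools.permutations(range(P), G):
            total = sum(cost[r, c] for c, r in enumerate(rows))
            if total < best_total - 1e-15:
                best_total = total
                best_pairs = sorted((r, c) for c, r in enumerate(rows))
    return best_pairs, float(best_total)


def topk_rounds_oracle(cost: np.ndarray, k: int) -> list[tuple[int, int]]:
    """k explicit one-to-one rounds over a shrinking prediction pool.

    Each round is solved by the brute-force permutation oracle, so this stays
    independent of both scipy and the package's Top-K implementation.
    """
    pool = list(range(cost.shape[0]))
    pairs: list[tuple[int, int]] = []
    for _ in range(k):
        if not pool or cost.shape[1] == 0:
            break
        sub = cost[pool]
        round_pairs, _ = hungarian_oracle(sub)
        assigned = []
        for p_sub, g in round_pairs:
            pairs.append((pool[p_sub], g))
            assigned.append(pool[p_sub])
        pool = [p for p in pool if p not in assigned]
    return sorted(pairs)


# ---------------------------------------------------------------------------
# progressive pyramid (straight-line numpy recomputation)
# ---------------------------------------------------------------------------

def conv2d_loops(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                 stride: int = 1, padding: int = 0) -> np.ndarray:
    """Naive nested-loop convolution."""
    c_out, c_in, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    h_out = (xp.shape[1] - kh) // stride + 1
    w_out = (xp.shape[2] - kw) // stride + 1
    out = np.zeros((c_out, h_out, w_out))
    for o in range(c_out):
        for i in range(h_out):
            for j in range(w_out):
                patch = xp[:, i * stride:i * stride + kh, j * stride:j * stride + kw]
                out[o, i, j] = (patch * w[o]).sum() + b[o]
    return out


def sigmoid_np(x):
    return 1.0 / (1.0 + np.exp(-x))


def top_transform_oracle(level, top_module) -> np.ndarray:
    """Recompute the coarsest-level transform stage by stage."""
    y = conv2d_loops(level, top_module.fc_in.weight.data, top_module.fc_in.bias.data)
    y = conv2d_loops(y, top_module.conv.weight.data, top_module.conv.bias.data, padding=1)
    return conv2d_loops(y, top_module.fc_out.weight.data, top_module.fc_out.bias.data)


def afa_oracle(p1: np.ndarray, p2: np.ndarray, afa) -> dict:
    """Recompute the spatial gate, channel gate and fused output of one AFA."""
    fs = sigmoid_np(conv2d_loops(p1, afa.squeeze1.weight.data, afa.squeeze1.bias.data)
                    + conv2d_loops(p2, afa.squeeze2.weight.data, afa.squeeze2.bias.data))
    p12 = np.concatenate([p1, p2], axis=0)
    pooled = p12.mean(axis=(1, 2))
    pc = sigmoid_np(pooled @ afa.excite.weight.data + afa.excite.bias.data)
    weighted = p12 * pc[:, None, None]
    fc = conv2d_loops(weighted, afa.reduce.weight.data, afa.reduce.bias.data)
    return {"spatial": fs, "channel_weights": pc, "channel": fc, "fused": fc * fs}


def upsample_nearest_oracle(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    c, h, w = x.shape
    out = np.zeros((c, out_h, out_w))
    for i in range(out_h):
        for j in range(out_w):
            out[:, i, j] = x[:, i * h // out_h, j * w // out_w]
    return out


def progressive_fuse_oracle(levels: list[np.ndarray], fpn) -> list[np.ndarray]:
    """Hand-unrolled top-down fusion: top transform, then AFA per lower level."""
    out: list[np.ndarray] = [None] * len(levels)  # type: ignore[list-item]
    out[-1] = top_transform_oracle(levels[-1], fpn.top)
    for i in range(len(levels) - 2, -1, -1):
        _, h, w = levels[i].shape
        up = upsample_nearest_oracle(out[i + 1], h, w)
        out[i] = afa_oracle(levels[i], up, fpn.afas[i])["fused"]
    return out


# ---------------------------------------------------------------------------
# COCO-protocol evaluator (accumulation-style, single category)
# ---------------------------------------------------------------------------

def coco_eval_oracle(dets_per_image: dict, gts_per_image: dict,
                     iou_thresholds: np.ndarray, max_dets: int,
                     recall_budgets: tuple[int, ...] = (100, 300)) -> dict:
    """Reference evaluation following the COCO accumulation algorithm.

    Per image and IoU threshold, detections (score-sorted, capped) greedily
    claim the unmatched ground truth of highest IoU; match matrices are then
    concatenated across images in global score order, precision/recall curves
    accumulated, and AP read off a 101-point recall grid via the
    right-to-left precision maximum. AR@K is the final recall under a per-
    image cap of K, averaged over thresholds.
    """
    recall_grid = np.linspace(0.0, 1.0, 101)

    def match_image(dets, gts, thr, cap):
        order = sorted(range(len(dets)), key=lambda i: (-dets[i][1], i))[:cap]
        taken = [False] * len(gts)
        out = []
        for i in order:
            best_iou, best_g = thr - 1e-12, -1
            for g, gt in enumerate(gts):
                if taken[g]:
                    continue
                v = iou_scalar(dets[i][0], gt)
                if v > best_iou:
                    best_iou, best_g = v, g
            if best_g >= 0 and best_iou >= thr:
                taken[best_g] = True
                out.append((dets[i][1], True))
            else:
                out.append((dets[i][1], False))
        return out, sum(taken)

    aps, recalls_at = [], {b: [] for b in recall_budgets}
    img_ids = sorted(gts_per_image)
    total_gt = sum(len(gts_per_image[i]) for i in img_ids)
    for thr in iou_thresholds:
        records = []
        for rank, img_id in enumerate(img_ids):
            matched, _ = match_image(dets_per_image.get(img_id, []),
                                     gts_per_image[img_id], thr, max_dets)
            records.extend((-s, rank, j, f) for j, (s, f) in enumerate(matched))
        records.sort()
        flags = np.array([r[3] for r in records], dtype=bool)
        if total_gt == 0 or flags.size == 0:
            aps.append(0.0)
        else:
            tp = np.cumsum(flags)
            fp = np.cumsum(~flags)
            rc = tp / total_gt
            pr = tp / (tp + fp)
            for i in range(len(pr) - 1, 0, -1):
                pr[i - 1] = max(pr[i - 1], pr[i])
            inds = np.searchsorted(rc, recall_grid, side="left")
            q = np.zeros(101)
            for ri, pi in enumerate(inds):
                if pi < len(pr):
                    q[ri] = pr[pi]
            aps.append(q.mean())
        for budget in recall_budgets:
            tp_b = 0
            for img_id in img_ids:
                _, n_matched = match_image(dets_per_image.get(img_id, []),
                                           gts_per_image[img_id], thr, budget)
                tp_b += n_matched
            recalls_at[budget].append(tp_b / total_gt if total_gt else 0.0)
    return {
        "mAP": float(np.mean(aps)),
        "mAP@50": float(aps[0]),
        "mAP@75": float(aps[5]),
        **{f"AR@{b}": float(np.mean(v)) for b, v in recalls_at.items()},
    }


# ---------------------------------------------------------------------------
# auxiliary head helpers
# ---------------------------------------------------------------------------

def adapter_index_oracle(memory: np.ndarray, shapes) -> list[np.ndarray]:
    """Element-by-element index arithmetic mapping memory rows to grids."""
    levels = []
    offset = 0
    for c, h, w in shapes:
        grid = np.zeros((c, h, w))
        for row in range(h):
            for col in range(w):
                token = offset + row * w + col
                for ch in range(c):
                    grid[ch, row, col] = memory[token, ch]
        levels.append(grid)
        offset += h * w
    return levels


def sinusoid_oracle(values: np.ndarray, dim: int, temperature: float = 10000.0) -> np.ndarray:
    """Straight-line recomputation of the sin/cos positional embedding."""
    per_coord = dim // 4
    out = np.zeros((values.shape[0], dim))
    for n in range(values.shape[0]):
        feats = []
        for coord in range(4):
            sines, cosines = [], []
            for i in range(per_coord // 2):
                freq = 1.0 / temperature ** (2 * i / per_coord)
                angle = 2 * np.pi * values[n, coord] * freq
                sines.append(np.sin(angle))
                cosines.append(np.cos(angle))
            feats.extend(sines + cosines)
        out[n] = feats
    return out
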