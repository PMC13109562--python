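# Methods

This note records the models and procedures `denseleaf` implements, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions taken where the design was open.

## Box geometry and suppression

Boxes are continuous, origin top-left, corner-form `(x0, y0, x1, y1)` with
area `(x1−x0)(y1−y0)` and no `+1` correction — the COCO convention, which the
metrics module must reproduce exactly. IoU of a pair with zero union is 0 by
convention; GIoU is `IoU − (enclosure − union)/enclosure`, in `(−1, 1]`.

Class-agnostic NMS is greedy descending-score suppression ignoring labels.
Ties on equal scores break toward the lower original index so results are
deterministic. Wherever a suppression threshold is needed but not otherwise
specified, the default is IoU 0.7 — a common crowded-scene choice, exposed in
configuration throughout.

## Matching

The matching cost follows the DETR-family convention,
`w_cls(1−p) + w_l1‖b−g‖₁ + w_giou(1−GIoU)` with defaults
`w_cls = 2, w_l1 = 5, w_giou = 2`, boxes in normalized center form. One-to-one
matching is solved by `scipy.optimize.linear_sum_assignment`.

**Top-K Hungarian matching** replicates each ground truth `k` times,
implemented as `k` sequential one-to-one rounds: predictions assigned in an
earlier round leave the pool before the next round, giving
`|pairs| = min(k·G, P)` and at most `k` predictions per ground truth. The
default `k = 4` balances supervision density against label noise; the valid
range is 1–8. Note that enlarging the prediction pool can only lower the
optimal total cost when predictions already outnumber ground truths; with
fewer predictions than ground truths, adding a prediction adds a pair and
may raise the total — the monotonicity property is only meaningful in the
overcomplete regime in which query detectors operate.

**Crowded query refinement** applies NMS culling once, to the final decoder
outputs of the original branch, before one-to-one matching; a per-stage
culling variant would also be defensible, but the single-pass form is the
simpler reading and is the default. Extra queries are ranked by
classification score (sigmoid of the foreground logit), never NMS-filtered,
and matched by Top-K Hungarian. Their loss enters with weight
`extra_loss_weight = 0.5` ("lower weight" being otherwise unquantified). The
extra-query count defaults to the original-query count. The extra branch
shares decoder weights with the original branch in the miniature model; this
is a deliberate simplification and is flagged here because weight sharing is
an open design choice.

## Progressive pyramid fusion

The coarsest level passes through a feed-forward transform read as
1×1 conv → 3×3 conv (padding 1) → 1×1 conv; kernel sizes are not dictated by
the fusion scheme itself, so the standard pyramid-block reading is used, with
the hidden width equal to the channel count `C`. Each finer level is fused
with the 2× upsampled level above via AFA:

* spatial gate: `sigmoid(Conv₁ₓ₁(P1) + Conv₁ₓ₁(P2))` with `C→1` channels —
  one attention value per location, strictly in (0, 1);
* channel gate: concatenate to `2C` channels, global average pool, a linear
  map `2C→2C` (equivalently a 1×1 convolution on the pooled vector) and a
  sigmoid give per-channel weights; the reweighted concatenation is reduced
  `2C→C` by a 1×1 convolution;
* fused output: elementwise product of the channel-gated map and the
  broadcast spatial gate.

No normalization is inserted before the spatial-gate addition. Upsampling is
nearest-neighbour by default (bilinear available); odd-size mismatches are
resolved by resampling to the finer level's exact height and width. Fusion is
strictly sequential top→bottom, so each output level depends on every level
above it — permuting levels changes the result, which the tests verify.

All of this runs on the package's own reverse-mode autodiff core
(`denseleaf._autodiff`): float64 tensors over numpy with broadcasting
arithmetic, im2col convolution, and nearest/bilinear resampling primitives.
Gradient correctness is pinned by central-difference checks (observed
agreement ~1e−6 relative; the test bound is 1e−3).

## Auxiliary-head injection

The adapter unflattens encoder memory (tokens ordered level-by-level,
row-major, channels last) back into `(C, H, W)` grids; it is the exact
inverse of flattening. The desk-scale stand-in head proposes jittered
anchors around activation peaks of the finest level, sized around the median
ground-truth extent, and keeps proposals with IoU ≥ 0.5 against any ground
truth — one-to-many by construction. Full single-/two-stage auxiliary heads
are out of scope.

Pooled positives are then assigned confidences drawn i.i.d. from U(0, 1) —
the heads' own confidences are discarded entirely rather than mixed, so that
easy high-confidence surface leaves cannot monopolize the injection — and
suppressed by the same class-agnostic NMS, sharing the single configured
threshold. Survivors are encoded by a fixed sinusoidal embedding of their
normalized center-form coordinates (dimension = the decoder query width,
temperature 10000) and injected as additional decoder queries; injected
queries join the extra pool for one-to-many supervision.

## Metrics

The operative AP definition is the COCO dialect: 101-point interpolation of
the precision envelope, averaged over IoU thresholds 0.50:0.05:0.95, with a
per-image cap of 100 detections inside AP; the literal trapezoid integral of
P(R) is available as `interpolation="continuous"`. AR@K is the final recall
under a per-image cap of K detections, averaged over the same IoU grid —
AR@300 ≥ AR@100 holds by construction. Standalone precision/recall/F1 are
reported at IoU 0.5 with a score threshold of 0.5 (the threshold is
configurable; 0.5 is a neutral operating point). There is a single
foreground class, so the class average in mAP is over one class. The test
suite cross-checks `summarize` against an independently coded evaluator that
follows the COCO accumulation algorithm, to 1e−6.

## Synthetic scenes

Leaves are textured ellipses with a midrib line, a per-leaf brightness
factor, and an additive two-sided illumination difference across the midrib
— the minimal shape family exhibiting the challenges of interest: heavy
overlap, near-identical texture between neighbours, and split illumination.
Instance counts are Poisson with mean 50 by default (matching the ~50
objects-per-image density regime without fixing every scene); rendering is
back-to-front so later leaves occlude earlier ones, and per-leaf visibility
is exact pixel counting on the instance label map. A leaf's "full area" is
its ellipse clipped to the canvas. Annotation boxes tightly bound the
*visible* pixel set only (pixel `(r, c)` occupies `[c, c+1) × [r, r+1)`), and
leaves below the minimum visible fraction — area fraction, default 1/3 — are
unannotated. The 1/3 rule is applied to visible *area*; a length-based
reading of "1/3 of the blade" would also be possible, but area is the
well-defined quantity on a pixel mask.

What the generator does **not** emulate: real leaf shape variation, serrated
edges, disease lesions, specular highlights, camera optics, or perspective;
scene sizes are desk-scale (default 256×256) rather than the 61-megapixel
frames of real aerial capture. Passing tests therefore demonstrate the
correctness of the algorithms under the stated density/occlusion statistics,
not detection accuracy on real canopy photographs.

## Dataset pipeline

Sliding windows advance per axis in steps of 5000 px while a 9504×6336
window fits; a final origin is clamped to `source − window` when coverage
would otherwise fall short, guaranteeing full pixel coverage. Boxes clipped
by a window are kept only if at least 1/3 of their area remains — the crop
rule reuses the visibility convention, since no separate crop-boundary rule
is specified anywhere. Tiles with fewer than 50 boxes are rejected; the same
predicate with a minimum of 200 screens whole source images. Semantic
screening (roads, people, edge-scattered layouts) requires human judgment
and is out of scope.

Density is boxes/images **truncated** (not rounded) to two decimals:
85375/1696 = 50.339 must print 50.33, which only truncation produces, and
that convention is applied uniformly even though published comparison tables
are not internally consistent about it (e.g. 339565/15000 = 22.6377 printed
as 22.64).

## Miniature detector and training

The encoder/decoder stand-ins are deliberately minimal — the novelty lives in
the pyramid, the matcher and the injection, and the stand-in exists to
exercise them end-to-end on a CPU. Backbone: a stride-2 stem plus one
stride-2 stage per pyramid level (uniform width `C`). Encoder: flattened
memory through a residual linear-ReLU layer. Decoder: learnable query
embeddings, single-head cross-attention plus a position-wise feed-forward
layer (1–2 layers), heads emitting a sigmoid-normalized center-form box and
one foreground logit. The classification bias is initialized to −2 (a
rare-foreground prior). Loss on matched pairs: sigmoid focal classification
(α = 0.25, γ = 2) + 5·L1 + 2·(1−GIoU), the convention consistent with the
matcher weights. Library default is 300 original queries; the tests and the
acceptance script run a smaller instantiation (C = 16, 2 levels, 40 + 40
queries, 64×64 scenes at mean density 10, 200 iterations) — these problem
sizes are the package's chosen desk scale.

Training follows AdamW-style Adam at learning rate 2e−4, weight decay 1e−4,
gradient clipping by global L2 norm at 0.1, a 12-epoch schedule with a 10×
learning-rate drop at epoch 11 (mapped proportionally onto short
fixed-iteration runs), and an 8:2 train/validation split. All initialization
and data randomness is seeded; identical seeds reproduce loss trajectories
bit-for-bit. Divergence (non-finite loss) raises rather than being silently
recorded.

## Known limitations

* The autodiff core implements exactly the primitives the model needs; it is
  not a general framework (no batching dimension — images are processed one
  at a time — and no GPU path).
* The stub auxiliary head is a geometric stand-in; conclusions about JTAH
  concern the randomized-confidence injection pipeline, not any particular
  head architecture.
* Metrics implement the single-class, no-crowd, all-area-range slice of the
  COCO protocol — sufficient here, not a general COCO evaluator.
* The miniature detector demonstrates mechanism (loss reduction, supervision
  multiplication, ablation sensitivity), not competitive accuracy; no claim
  about full-scale detection quality follows from it.
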