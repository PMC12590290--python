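# Methods

## Problem setting

Single-particle cryo-EM reconstruction begins by locating tens of thousands
of individual macromolecule projections ("particles") in 2D micrographs that
are extremely noisy, densely packed, and contaminated by ice and debris.
`gtpick` treats picking as set prediction: a detector proposes a fixed
budget of candidate boxes per micrograph, a bipartite matching assigns
proposals to annotated particles during training, and at inference the
surviving centers are exported as RELION-style `.star` coordinates that
CryoSPARC can extract from directly.

## Model

**Backbone.** A convolutional backbone maps a standardized (zero-mean,
unit-variance) grayscale micrograph to a coarse feature map `X ∈
R^{B×C×H×W}`. The default is a ResNet-101 (bottleneck blocks [3, 4, 23, 3],
stride 32) in which every batch-norm layer is replaced by a frozen variant:
statistics and affine terms are fixed buffers, nothing is trainable, and no
batch statistics are ever computed — batch sizes of 1–2 make live statistics
meaningless. No pretrained weights ship with the package; a checkpoint can
be loaded through the standard state-dict mechanism. For CPU-scale work a
"tiny" stride-16 backbone is provided: a 4× average-pooling stem (averaging
is the matched filter for blob-like particles in white noise), two stride-2
conv blocks (He-initialized — ReLU stacks under Xavier initialization shrink
activations several-fold per layer, leaving the image signal far below the
positional code), and a fixed local-mean pyramid (16, 8 and 4 px averages,
the finer scales folded into channels by space-to-depth) that delivers local
intensity, including its sub-token layout, to every feature-map cell even at
random initialization.

**Encoder.** The feature map is flattened to an `HW×B×C` token sequence,
summed once with a fixed 2D sinusoidal positional code `P` (interleaved
sin/cos over a geometric frequency ladder; positions normalized so column
`j` maps to `2πj/W`), and passed through post-norm transformer layers
(self-attention, feed-forward, residual + LayerNorm, dropout before each
LayerNorm).

**Decoder with grouped queries and dynamic reference points.** The decoder
refines `Q = G × Qg` learned queries in `N` layers of self-attention,
cross-attention and feed-forward, each with residual + LayerNorm. Queries
are partitioned into `G` groups; a block-diagonal self-attention mask keeps
groups mutually invisible, so the decoder is exactly equivalent to `G`
independent single-group decoders with shared weights (a tested invariant).
The mask is applied in both training and evaluation mode so inference sees
the same computation the queries were trained under.

Each query owns a reference point — a normalized 2D location, initialized
on a jittered grid per group and stored in logit space so it stays in
(0, 1). The reference point conditions cross-attention three ways:

1. its sinusoidal encoding (same family and scale as `P`) is added to the
   cross-attention query;
2. a Gaussian locality bias `−‖p_token − p_ref‖² / 2σ²` is added to the
   attention logits, with a learnable per-layer log-σ initialized
   coarse-to-fine (σ₀ = 0.25 of the frame, quartered per layer), so early
   layers search broadly and late layers commit to the nearest particle;
3. a *token-objectness gate* — a linear map from each memory token to a
   scalar — is added to the same logits, so particle-bearing tokens draw
   attention within the locality window.

After the bias is formed, the reference point is updated *dynamically*: it
moves to the center of mass of its own locality-gated attention profile (a
soft-argmax over token positions), and its encoding is recomputed. The
updated point is both the next layer's reference and the anchor of the box
prediction. These three mechanisms exist because the minimal alternative —
reference encoding added to the query only, attention left to discover
spatial alignment through its bilinear q·k form — does not converge in the
few thousand optimizer steps a desk-scale run affords: with near-uniform
attention weights the attended value is *linear* in the memory and cannot
encode particle positions at all, so training stalls at the best
image-independent prediction.

**Heads.** A linear head with sigmoid gives the per-query particle
probability (single foreground class; no softmax background). A 3-layer MLP
predicts the box: center offsets are added to the inverse-sigmoid of the
reference point before the sigmoid squash (zero offsets ⇒ box centered on
the reference point), and widths/heights are squashed independently with the
final bias initialized at −2 (particles occupy a small fraction of any
frame). Every decoder layer emits predictions; auxiliary losses supervise
all of them (flag-controlled, default on).

## Matching and loss

Within each group, a minimum-cost bipartite assignment (scipy's Hungarian
solver) pairs queries with ground-truth boxes; the union over groups gives
each particle up to `G` positive queries — one-to-many supervision that
raises recall in crowded micrographs. The pair cost is
`λ_cls·(−p) + λ_L1·‖b̂−b‖₁ + λ_GIoU·(1−GIoU)`, with the loss weights reused
as cost weights; the published objective names Hungarian matching but not a
cost, so this is the package's choice (the simple `−p` classification term
rather than a focal-shaped one). If a micrograph holds more particles than a
group has queries, the surplus targets go unmatched in that group (logged).

The training objective is the weighted sum

```
L_total = λ_cls·L_cls + λ_L1·L_L1 + λ_GIoU·L_GIoU,
λ_cls = 2, λ_L1 = 5, λ_GIoU = 2
```

with `L_cls` the binary focal loss `−Σ α_t (1−p_t)^γ log p_t` (α = 0.25,
γ = 2) summed over all queries, and `L_L1`, `L_GIoU` means over the `N`
matched pairs of the normalized-coordinate L1 distance and `1 − GIoU`.
`L_cls` is also normalized by `N` — the raw focal sum is otherwise
incommensurate with the two box terms; anyone comparing absolute loss
magnitudes against full-scale training curves should account for this.
Scores are clamped to `[1e−8, 1−1e−8]` before the log.

One additional term aids optimization only: the objectness gate of each
decoder layer is supervised with a binary cross-entropy against a soft
heatmap in which every ground-truth center is splat bilinearly onto its four
surrounding tokens (weight 1.0, flag `gate_supervision`). Calibrating the
gate this way makes the soft-argmax reference update recover sub-token
positions, and it breaks the bootstrap deadlock in which attention cannot
learn to peak until the box head can decode positions and vice versa.
`L_total` as reported in the loss history remains exactly the three-term sum
above.

## Training

Defaults follow the full-scale recipe: 640×640 inputs, AdamW, learning rate
1e−4 with 1e−5 for the backbone, weight decay 1e−4, batch size 2, Xavier
initialization for all transformer weights, dropout 0.1 before each
LayerNorm. Horizontal/vertical flips and a transpose (together, the full
dihedral group — micrographs have no preferred orientation) augment
training images; boxes transform exactly because they are normalized.
Gradients are clipped to a global norm of 5. The validation metric for
checkpoint selection is F1 under the evaluation module's default criterion.
Training is fully seeded (init, data order, augmentation, dropout): the same
seed reproduces the loss history bit for bit on CPU.

Two defaults deliberately deviate from the full-scale recipe when the
backbone is randomly initialized (as in the desk-scale benchmark): the
backbone learning-rate tier is pointless without pretrained weights, and a
~10⁵-parameter model on a few hundred images tolerates a larger step, so
the benchmark config uses 1e−3 for both tiers.

## Inference

The micrograph is resized whole to the model input size (no tiling; a
config extension point). Final-layer predictions from *all* groups are
thresholded (default score ≥ 0.5) and pooled across the four dihedral views
of the image (test-time merging, flag `tta`): each view lands the query grid
differently, filling coverage gaps, and the back-transformed centers of the
same particle average out localization noise. Candidates are clustered
greedily in descending score order with radius 0.5 × the mean ground-truth
box side of the training set (stored in the checkpoint); each cluster
becomes one pick at its score-weighted centroid with the maximum member
score, and clusters with fewer than `min_votes = 3` members are dropped —
one-to-many training plus view merging give a real particle ~`G×4` votes,
while spurious detections are view-idiosyncratic. Centers are mapped back
to original micrograph pixels and always lie inside the frame.

## Evaluation

A pick matches an unclaimed ground-truth particle when the center distance
is at most half the truth box's mean side (the criterion is configurable to
IoU ≥ 0.5, which requires predicted boxes); matching is greedy in descending
score order, earlier index winning ties. Counts are pooled over micrographs
(micro-average) within a dataset; across datasets the arithmetic mean of
per-dataset metrics is reported. `tp + fn = |truth|` and `tp + fp = |preds|`
hold by construction.

## Synthetic benchmark

The simulator renders dark (configurable polarity) soft-edged disks of
radius 8 ± 2 px on a slowly varying cosine background, at 5–15 particles
per 128 px frame with centers ≥ 12 px apart, plus two larger elliptical
contamination blobs that are *not* annotated (false-positive pressure) and
never overlap an annotated box, under additive Gaussian noise of 0.8 × the
particle contrast. Ground truth is the tight square of side `2r` per
particle; every image is a pure function of (config, seed, index). It does
not model CTF oscillations, radiation damage, ice gradients, or real
projection structure — benchmark results demonstrate that the machinery
works end to end, not that published full-scale numbers transfer.

The standard benchmark simulates 250 micrographs (200/25/25 by hashing the
index, an 8:1:1 split), trains the tiny configuration (hidden dim 64, 1
encoder + 2 decoder layers, G = 2 groups × Qg = 10 queries, tiny backbone)
for 20 epochs at batch 2, and reports precision/recall/F1 on the 25
held-out images. Note `Qg = 10` caps per-group recall in frames with more
than 10 particles; the pooled attainable recall under these conditions is
about 0.95.

## Numerical choices

* Degenerate zero-area boxes are rejected at construction; GIoU therefore
  never divides by zero.
* Inverse-sigmoid anchoring clamps to `[1e−6, 1−1e−6]`.
* Per-micrograph standardization floors the variance at 1e−8; constant
  frames become all zeros.
* COCO boxes protruding more than 1 px beyond the frame are clamped with a
  warning; sub-pixel protrusions are clamped silently.
* Hungarian ties resolve to the solver's lowest-index solution;
  equal-score picks match in input order.
* All computation is float64 on CPU; checkpoints round-trip bitwise.

## Known limitations

* No pretrained backbone is distributed; full-scale accuracy on real
  micrographs therefore requires training from user-supplied annotations.
* One box size per detection; elongated or multi-species samples are out of
  scope (single foreground class).
* Micrographs are resized whole; extremely large frames trade resolution
  for speed unless the tiling extension point is implemented.
* The `.star` writer emits coordinates and a figure of merit only. A picker
  has no particle pose, so no rotation-angle columns are written; CryoSPARC
  import does not require them. Coordinates are particle centers, 0-based,
  origin top-left — re-check the convention before use with display tools
  that assume otherwise.
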