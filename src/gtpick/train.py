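"""Training loop and inference for the particle detector.

Training follows the detector's published recipe: AdamW with a main
learning rate and a lower backbone rate, weight decay 1e-4, batch size 2,
Xavier-initialized weights, square model inputs (default 640 px), dropout
0.1 before every LayerNorm. Auxiliary losses supervise every decoder layer.
Checkpoint selection uses F1 on the validation split.

Inference resizes each micrograph to the model input size, thresholds the
final-layer scores, merges the predictions of all query groups, and removes
the near-duplicates one-to-many training deliberately creates with a greedy
score-descending radius suppression. Surviving centers are mapped back to
original micrograph pixel coordinates.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .evaluation import MatchCriterion, evaluate_dataset
from .io_formats import AnnotationSet, MicrographRecord, PickedParticle
from .losses import FocalParams, LossBreakdown, LossWeights, detection_loss
from .model import ParticleDetector
from .nn import Tensor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    input_size: int = 640
    lr_main: float = 1e-4
    lr_backbone: float = 1e-5
    weight_decay: float = 1e-4
    batch_size: int = 2
    epochs: int = 50
    seed: int = 0
    grad_clip: float = 5.0
    flip_augment: bool = True
    gate_supervision: float = 1.0  # weight of the token-objectness training aid
    weights: LossWeights = field(default_factory=LossWeights)
    focal: FocalParams = field(default_factory=FocalParams)

    def __post_init__(self):
        if min(self.lr_main, self.lr_backbone, self.weight_decay) <= 0:
            raise ValueError("rates must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass(frozen=True)
class InferConfig:
    score_threshold: float = 0.5
    dedup_radius: float = 0.5     # fraction of the mean ground-truth box side
    group_mode: str = "all_merged"  # or "first_group"
    tta: bool = True              # merge picks over the 4 flip/transpose views
    min_votes: int = 3            # with tta: drop clusters with fewer members

    def __post_init__(self):
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")
        if self.group_mode not in {"all_merged", "first_group"}:
            raise ValueError("group_mode must be 'all_merged' or 'first_group'")


@dataclass
class Sample:
    """One training example: standardized image + normalized target boxes."""

    image: np.ndarray          # (H, W) float
    boxes: np.ndarray          # (T, 4) center-form normalized
    micrograph_id: str = ""


def samples_from_annotations(records: list[MicrographRecord],
                             annos: AnnotationSet) -> list[Sample]:
    by_id = {r.micrograph_id: r for r in records}
    samples = []
    for mid, record in by_id.items():
        boxes = np.array([b.as_array() for b in annos.boxes_for(mid)]).reshape(-1, 4)
        samples.append(Sample(image=record.image, boxes=boxes, micrograph_id=mid))
    return samples


def resize_and_augment(image: np.ndarray, boxes: np.ndarray, input_size: int,
                       rng: np.random.Generator | None = None,
                       flips: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Resize to the square model input; optional box-consistent flips.

    Boxes are normalized, so a pure resize leaves them untouched; flips
    mirror the coordinates exactly.
    """
    if image.shape != (input_size, input_size):
        image = _sk_resize(image, (input_size, input_size), order=1,
                           anti_aliasing=True, preserve_range=True)
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4).copy()
    if flips and rng is not None:
        if rng.random() < 0.5:
            image = image[:, ::-1]
            boxes[:, 0] = 1.0 - boxes[:, 0]
        if rng.random() < 0.5:
            image = image[::-1, :]
            boxes[:, 1] = 1.0 - boxes[:, 1]
        if rng.random() < 0.5:  # transpose: with the flips, the full dihedral group
            image = image.T
            boxes = boxes[:, [1, 0, 3, 2]]
    return np.ascontiguousarray(image), boxes


def _token_objectness_targets(targets: list[np.ndarray], grid: tuple[int, int]
                              ) -> np.ndarray:
    """(HW, B, 1) soft heatmap: each ground-truth center splat bilinearly
    onto the four surrounding token cells, so a soft-argmax over calibrated
    gate activations can recover sub-token center positions."""
    fh, fw = grid
    out = np.zeros((fh * fw, len(targets), 1))
    for b, boxes in enumerate(targets):
        for cx, cy, _, _ in boxes:
            u = cx * fw - 0.5
            v = cy * fh - 0.5
            j0, i0 = int(np.floor(u)), int(np.floor(v))
            fu, fv = u - j0, v - i0
            for di, dj, wgt in ((0, 0, (1 - fv) * (1 - fu)), (0, 1, (1 - fv) * fu),
                                (1, 0, fv * (1 - fu)), (1, 1, fv * fu)):
                i, j = i0 + di, j0 + dj
                if 0 <= i < fh and 0 <= j < fw:
                    k = i * fw + j
                    out[k, b, 0] = max(out[k, b, 0], wgt)
    return out


def _gate_loss(model: ParticleDetector, targets: list[np.ndarray]) -> Tensor | None:
    """Binary cross-entropy pushing each layer's attention gate toward the
    particle-bearing tokens; a bootstrap aid that gives cross-attention a
    direct learning signal before box regression can provide one."""
    y = None
    total = None
    n = 0
    for layer in model.decoder_layers:
        z = layer.last_gate_logits
        if z is None:
            continue
        if y is None:
            y = _token_objectness_targets(targets, model.last_grid)
        bce = z.relu() - z * y + ((z.abs() * -1.0).exp() + 1.0).log()
        term = bce.mean()
        total = term if total is None else total + term
        n += 1
    return None if total is None else total * (1.0 / n)


def mean_box_side(samples: list[Sample]) -> float:
    """Mean of (w + h) / 2 over all ground-truth boxes, normalized units."""
    sides = [float((b[2] + b[3]) / 2.0) for s in samples for b in s.boxes]
    return float(np.mean(sides)) if sides else 0.1


def train(model: ParticleDetector, train_samples: list[Sample],
          val_samples: list[Sample], cfg: TrainConfig
          ) -> tuple[dict, list[dict]]:
    """Train in place; returns (best state dict, per-epoch loss history)."""
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    nn.manual_seed(cfg.seed + 1)  # dropout draws, independent of init stream

    backbone_params, main_params = [], []
    for name, p in model.named_parameters():
        (backbone_params if name.startswith("backbone.") else main_params).append(p)
    opt = nn.AdamW([
        {"params": main_params, "lr": cfg.lr_main},
        {"params": backbone_params, "lr": cfg.lr_backbone},
    ], weight_decay=cfg.weight_decay)

    side = mean_box_side(train_samples)
    infer_cfg = InferConfig()
    criterion = MatchCriterion()
    history: list[dict] = []
    best_f1, best_state = -1.0, model.state_dict()

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_samples))
        sums = np.zeros(4)
        n_matched_total = 0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_samples[i] for i in order[start:start + cfg.batch_size]]
            images, targets = [], []
            for s in batch:
                img, boxes = resize_and_augment(s.image, s.boxes, cfg.input_size,
                                                rng, flips=cfg.flip_augment)
                images.append(img)
                targets.append(boxes)
            x = Tensor(np.stack(images)[:, None, :, :])
            outputs = model(x)
            losses = []
            final_breakdown: LossBreakdown | None = None
            supervised = outputs if model.cfg.aux_loss else outputs[-1:]
            for scores, boxes in supervised:
                loss, breakdown = detection_loss(
                    scores, boxes, targets, model.group_of,
                    weights=cfg.weights, focal=cfg.focal)
                losses.append(loss)
                final_breakdown = breakdown
            total = losses[0]
            for extra in losses[1:]:
                total = total + extra
            if cfg.gate_supervision > 0:
                gate = _gate_loss(model, targets)
                if gate is not None:
                    total = total + cfg.gate_supervision * gate
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"{final_breakdown}")
            opt.zero_grad()
            total.backward()
            nn.clip_grad_norm(model.parameters(), cfg.grad_clip)
            opt.step()
            sums += [final_breakdown.l_cls, final_breakdown.l_l1,
                     final_breakdown.l_giou, final_breakdown.l_total]
            n_matched_total += final_breakdown.n_matched
            n_batches += 1
        entry = {
            "epoch": epoch,
            "l_cls": sums[0] / n_batches,
            "l_l1": sums[1] / n_batches,
            "l_giou": sums[2] / n_batches,
            "l_total": sums[3] / n_batches,
            "n_matched": n_matched_total,
        }
        if val_samples:
            entry["val_f1"] = _validation_f1(model, val_samples, cfg.input_size,
                                             infer_cfg, criterion, side)
            if entry["val_f1"] >= best_f1:
                best_f1 = entry["val_f1"]
                best_state = copy.deepcopy(model.state_dict())
        else:
            best_state = copy.deepcopy(model.state_dict())
        history.append(entry)
        logger.info("epoch %d: total %.4f (cls %.4f, l1 %.4f, giou %.4f)%s",
                    epoch, entry["l_total"], entry["l_cls"], entry["l_l1"],
                    entry["l_giou"],
                    f", val F1 {entry['val_f1']:.3f}" if "val_f1" in entry else "")
    model.load_state_dict(best_state)
    return best_state, history


def _validation_f1(model, val_samples, input_size, infer_cfg, criterion, side) -> float:
    from .geometry import Box
    from .io_formats import AnnotationRecord, ImageInfo

    truth = AnnotationSet()
    preds: list[PickedParticle] = []
    for i, s in enumerate(val_samples):
        h, w = s.image.shape
        name = s.micrograph_id or f"val_{i:04d}"
        truth.images[name] = ImageInfo(id=i + 1, file_name=name, width=w, height=h)
        for b in s.boxes:
            truth.records.append(AnnotationRecord(micrograph_id=name, box=Box(*b)))
        record = MicrographRecord(image=s.image, micrograph_id=name, width=w, height=h)
        preds.extend(pick(model, record, infer_cfg, mean_gt_box_side=side,
                          input_size=input_size))
    report, _ = evaluate_dataset(preds, truth, criterion)
    return report.f1


def pick(model: ParticleDetector, record: MicrographRecord,
         cfg: InferConfig = InferConfig(), *, mean_gt_box_side: float = 0.1,
         input_size: int | None = None) -> list[PickedParticle]:
    """Detect particles on one micrograph; centers in original pixel space."""
    model.eval()
    if input_size is None:
        input_size = max(record.image.shape)
    image, _ = resize_and_augment(record.image, np.zeros((0, 4)), input_size)

    # views of the dihedral group (image transform, center back-transform);
    # each view lands the query grid differently, so merging views fills
    # coverage gaps and averages out localization noise
    views = [(lambda im: im, lambda cx, cy: (cx, cy))]
    if cfg.tta:
        views += [
            (lambda im: im[:, ::-1], lambda cx, cy: (1.0 - cx, cy)),
            (lambda im: im[::-1, :], lambda cx, cy: (cx, 1.0 - cy)),
            (lambda im: im.T, lambda cx, cy: (cy, cx)),
        ]
    all_scores, all_cx, all_cy = [], [], []
    for fwd, back in views:
        view = np.ascontiguousarray(fwd(image))
        with nn.no_grad():
            outputs = model(Tensor(view[None, None, :, :]))
        scores, boxes = outputs[-1]
        scores = scores.data[:, 0]
        boxes = boxes.data[:, 0, :]
        if cfg.group_mode == "first_group":
            keep = model.group_of == 0
            scores, boxes = scores[keep], boxes[keep]
        keep = scores >= cfg.score_threshold
        cx, cy = back(boxes[keep, 0], boxes[keep, 1])
        all_scores.append(scores[keep])
        all_cx.append(cx)
        all_cy.append(cy)
    scores = np.concatenate(all_scores)

    width, height = record.width, record.height
    xs = np.clip(np.concatenate(all_cx) * width, 0.0, np.nextafter(width, 0.0))
    ys = np.clip(np.concatenate(all_cy) * height, 0.0, np.nextafter(height, 0.0))

    radius = cfg.dedup_radius * mean_gt_box_side * float(np.sqrt(width * height))
    order = np.argsort(-scores, kind="stable")
    clusters: list[list[int]] = []
    for i in order:
        for cluster in clusters:
            lead = cluster[0]
            if np.hypot(xs[i] - xs[lead], ys[i] - ys[lead]) <= radius:
                cluster.append(i)
                break
        else:
            clusters.append([i])
    # grouped one-to-many training deliberately produces one pick per group
    # per particle (times the merged views); merge each cluster into its
    # score-weighted centroid, dropping weakly supported clusters — a real
    # particle draws picks from most groups and views, a spurious one rarely
    if cfg.tta and cfg.min_votes > 1:
        clusters = [c for c in clusters if len(c) >= cfg.min_votes]
    picks = []
    for cluster in clusters:
        w = scores[cluster]
        x = float(np.clip(np.average(xs[cluster], weights=w), 0.0,
                          np.nextafter(width, 0.0)))
        y = float(np.clip(np.average(ys[cluster], weights=w), 0.0,
                          np.nextafter(height, 0.0)))
        picks.append(PickedParticle(micrograph_name=record.micrograph_id,
                                    x=x, y=y,
                                    score=float(np.clip(w.max(), 0.0, 1.0))))
    logger.info("%s: %d picks", record.micrograph_id, len(picks))
    return picks
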