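"""Group-wise Hungarian assignment and the Focal + L1 + GIoU objective.

Assignment: within each query group a minimum-cost bipartite matching pairs
queries with ground-truth particles (one-to-one); running it independently
per group gives every particle up to ``G`` positive queries (one-to-many
across groups). The pair cost combines classification confidence, an L1 box
distance in normalized coordinates, and a GIoU term.

Loss: matched queries are supervised with an L1 + GIoU regression objective
averaged over the ``N`` matched pairs; all queries contribute to a binary
focal classification loss ``-sum_i alpha_t (1 - p_t)^gamma log p_t``, which
down-weights the easy background majority. The focal sum is also normalized
by ``N`` so the three terms stay commensurate. The total is the weighted sum
``lambda_cls * L_cls + lambda_l1 * L_l1 + lambda_giou * L_giou``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Box, cxcywh_to_xyxy, giou_matrix
from .nn import Tensor, concatenate

logger = logging.getLogger(__name__)

EPS = 1e-8


@dataclass(frozen=True)
class LossWeights:
    """Weights of the three loss components (DETR-family defaults)."""

    lambda_cls: float = 2.0
    lambda_l1: float = 5.0
    lambda_giou: float = 2.0

    def __post_init__(self):
        if min(self.lambda_cls, self.lambda_l1, self.lambda_giou) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_cls == self.lambda_l1 == self.lambda_giou == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class FocalParams:
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class MatchResult:
    """Per-group (query_index, target_index) pairs; query indices are global."""

    pairs_by_group: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def all_pairs(self) -> list[tuple[int, int]]:
        return [p for pairs in self.pairs_by_group.values() for p in pairs]

    @property
    def n_matched(self) -> int:
        return sum(len(v) for v in self.pairs_by_group.values())


@dataclass
class LossBreakdown:
    l_cls: float
    l_l1: float
    l_giou: float
    l_total: float
    n_matched: int


# -- matching -----------------------------------------------------------------


def match_cost(score: float, pred_box: Box, target_box: Box,
               weights: LossWeights = LossWeights()) -> float:
    """Assignment cost for one candidate pair (lower is better)."""
    pred = pred_box.as_array()[None, :]
    tgt = target_box.as_array()[None, :]
    l1 = float(np.abs(pred - tgt).sum())
    g = float(giou_matrix(cxcywh_to_xyxy(pred), cxcywh_to_xyxy(tgt))[0, 0])
    return (weights.lambda_cls * (-score) + weights.lambda_l1 * l1
            + weights.lambda_giou * (1.0 - g))


def cost_matrix(scores: np.ndarray, boxes: np.ndarray, targets: np.ndarray,
                weights: LossWeights = LossWeights()) -> np.ndarray:
    """(Qg, T) assignment costs for arrays of center-form normalized boxes."""
    l1 = np.abs(boxes[:, None, :] - targets[None, :, :]).sum(axis=-1)
    g = giou_matrix(cxcywh_to_xyxy(boxes), cxcywh_to_xyxy(targets))
    return (weights.lambda_cls * (-scores[:, None]) + weights.lambda_l1 * l1
            + weights.lambda_giou * (1.0 - g))


def hungarian_match(costs: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-cost bipartite assignment; all targets matched when T <= Qg."""
    costs = np.asarray(costs, dtype=np.float64)
    if not np.all(np.isfinite(costs)):
        raise ValueError("cost matrix contains non-finite entries")
    n_queries, n_targets = costs.shape
    if n_targets > n_queries:
        logger.warning("more targets (%d) than queries (%d); %d targets unmatched",
                       n_targets, n_queries, n_targets - n_queries)
    rows, cols = linear_sum_assignment(costs)
    return sorted(zip(rows.tolist(), cols.tolist()))


def group_assign(scores: np.ndarray, boxes: np.ndarray, targets: np.ndarray,
                 group_of: np.ndarray,
                 weights: LossWeights = LossWeights()) -> MatchResult:
    """Independent Hungarian matching per group; union of matches returned.

    Each target thus receives up to one positive query per group. With no
    targets every query is background and the result is empty.
    """
    result = MatchResult()
    targets = np.asarray(targets, dtype=np.float64).reshape(-1, 4)
    for g in np.unique(group_of):
        idx = np.flatnonzero(group_of == g)
        if targets.shape[0] == 0:
            result.pairs_by_group[int(g)] = []
            continue
        costs = cost_matrix(scores[idx], boxes[idx], targets, weights)
        pairs = hungarian_match(costs)
        result.pairs_by_group[int(g)] = [(int(idx[q]), int(t)) for q, t in pairs]
    return result


# -- differentiable losses ----------------------------------------------------


def focal_loss(scores: Tensor, is_foreground: np.ndarray, params: FocalParams,
               n_matched: int) -> Tensor:
    """Binary focal loss summed over queries, normalized by ``n_matched``.

    ``p_t`` is the predicted probability of the TRUE class (``p`` for
    foreground queries, ``1 - p`` for background); ``alpha_t`` weighs the two
    classes. Scores are clamped to ``[eps, 1 - eps]`` first.
    """
    scores = Tensor._wrap(scores)
    fg = np.asarray(is_foreground, dtype=np.float64)
    p = scores.clamp(EPS, 1.0 - EPS)
    p_t = p * fg + (1.0 - p) * (1.0 - fg)
    alpha_t = params.alpha * fg + (1.0 - params.alpha) * (1.0 - fg)
    per_query = (p_t.log() * (1.0 - p_t) ** params.gamma) * alpha_t
    return -per_query.sum() * (1.0 / max(n_matched, 1))


def l1_box_loss(pred_boxes: Tensor, target_boxes: np.ndarray) -> Tensor:
    """Mean absolute coordinate error over matched pairs, normalized units."""
    pred_boxes = Tensor._wrap(pred_boxes)
    n = pred_boxes.shape[0]
    if n == 0:
        logger.debug("l1_box_loss: no matched pairs, contributing 0")
        return Tensor(0.0)
    return (pred_boxes - np.asarray(target_boxes)).abs().sum() * (1.0 / n)


def _corners(boxes_cxcywh: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    cx, cy = boxes_cxcywh[:, 0], boxes_cxcywh[:, 1]
    hw, hh = boxes_cxcywh[:, 2] * 0.5, boxes_cxcywh[:, 3] * 0.5
    return cx - hw, cy - hh, cx + hw, cy + hh


def _select_min(a: Tensor, b: Tensor) -> Tensor:
    mask = (a.data <= b.data).astype(np.float64)
    return a * mask + b * (1.0 - mask)


def _select_max(a: Tensor, b: Tensor) -> Tensor:
    mask = (a.data >= b.data).astype(np.float64)
    return a * mask + b * (1.0 - mask)


def pairwise_giou(pred_cxcywh: Tensor, target_cxcywh: np.ndarray) -> Tensor:
    """Differentiable GIoU of aligned box pairs (both in center form)."""
    pred_cxcywh = Tensor._wrap(pred_cxcywh)
    tgt = Tensor(np.asarray(target_cxcywh, dtype=np.float64))
    ax0, ay0, ax1, ay1 = _corners(pred_cxcywh)
    bx0, by0, bx1, by1 = _corners(tgt)
    iw = (_select_min(ax1, bx1) - _select_max(ax0, bx0)).relu()
    ih = (_select_min(ay1, by1) - _select_max(ay0, by0)).relu()
    inter = iw * ih
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    union = area_a + area_b - inter
    enc = (_select_max(ax1, bx1) - _select_min(ax0, bx0)) \
        * (_select_max(ay1, by1) - _select_min(ay0, by0))
    return inter / union - (enc - union) / enc


def giou_loss(pred_boxes: Tensor, target_boxes: np.ndarray) -> Tensor:
    """Mean of ``1 - GIoU`` over matched pairs; each term lies in [0, 2]."""
    pred_boxes = Tensor._wrap(pred_boxes)
    n = pred_boxes.shape[0]
    if n == 0:
        logger.debug("giou_loss: no matched pairs, contributing 0")
        return Tensor(0.0)
    return (1.0 - pairwise_giou(pred_boxes, target_boxes)).sum() * (1.0 / n)


def total_loss(l_cls, l_l1, l_giou, weights: LossWeights = LossWeights()):
    """Exact weighted sum of the three components (Tensor- or float-valued)."""
    return (weights.lambda_cls * l_cls + weights.lambda_l1 * l_l1
            + weights.lambda_giou * l_giou)


def detection_loss(scores: Tensor, boxes: Tensor, targets: list[np.ndarray],
                   group_of: np.ndarray,
                   weights: LossWeights = LossWeights(),
                   focal: FocalParams = FocalParams()) -> tuple[Tensor, LossBreakdown]:
    """Match and score one prediction set against a batch of target lists.

    ``scores``: (Q, B); ``boxes``: (Q, B, 4); ``targets[b]``: (T_b, 4)
    center-form normalized ground truth of batch item ``b``. Matching is
    done on detached values; losses are pooled over the batch with a single
    ``N = total matched`` normalizer.
    """
    n_batch = scores.shape[1]
    matched_pred, matched_tgt, fg_masks = [], [], []
    n_matched = 0
    for b in range(n_batch):
        tgt = np.asarray(targets[b], dtype=np.float64).reshape(-1, 4)
        match = group_assign(scores.data[:, b], boxes.data[:, b, :], tgt,
                             group_of, weights)
        fg = np.zeros(scores.shape[0])
        pairs = match.all_pairs
        n_matched += len(pairs)
        if pairs:
            q_idx = np.array([q for q, _ in pairs])
            t_idx = np.array([t for _, t in pairs])
            fg[q_idx] = 1.0
            matched_pred.append(boxes[q_idx, b, :])
            matched_tgt.append(tgt[t_idx])
        fg_masks.append(fg)
    l_cls = focal_loss(scores, np.stack(fg_masks, axis=1), focal, n_matched)
    if matched_pred:
        pred_cat = concatenate(matched_pred, axis=0)
        tgt_cat = np.concatenate(matched_tgt, axis=0)
        l_l1 = l1_box_loss(pred_cat, tgt_cat)
        l_giou = giou_loss(pred_cat, tgt_cat)
    else:
        l_l1 = Tensor(0.0)
        l_giou = Tensor(0.0)
    total = total_loss(l_cls, l_l1, l_giou, weights)
    breakdown = LossBreakdown(
        l_cls=float(l_cls.data), l_l1=float(l_l1.data), l_giou=float(l_giou.data),
        l_total=float(total.data), n_matched=n_matched)
    return total, breakdown
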