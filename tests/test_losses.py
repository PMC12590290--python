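"""Matching and the Focal + L1 + GIoU objective."""

import itertools
import math

import numpy as np
import pytest

from gtpick import nn
from gtpick.geometry import Box
from gtpick.losses import (
    FocalParams,
    LossWeights,
    cost_matrix,
    detection_loss,
    focal_loss,
    giou_loss,
    group_assign,
    hungarian_match,
    l1_box_loss,
    match_cost,
    pairwise_giou,
    total_loss,
)
from gtpick.nn import Tensor


def brute_force_assignment(costs: np.ndarray) -> float:
    """Exhaustive minimum assignment cost (queries >= targets)."""
    n_q, n_t = costs.shape
    best = math.inf
    for perm in itertools.permutations(range(n_q), n_t):
        best = min(best, sum(costs[q, t] for t, q in enumerate(perm)))
    return best


class TestHungarian:
    def test_single_entry(self):
        assert hungarian_match(np.array([[3.7]])) == [(0, 0)]

    def test_two_by_two(self):
        assert hungarian_match(np.array([[1.0, 2.0], [2.0, 1.0]])) == [(0, 0), (1, 1)]

    @pytest.mark.parametrize("size", [3, 4, 5, 6])
    def test_matches_brute_force(self, size, rng):
        for _ in range(25):
            costs = rng.normal(size=(size, size))
            pairs = hungarian_match(costs)
            total = sum(costs[q, t] for q, t in pairs)
            assert total == pytest.approx(brute_force_assignment(costs))

    def test_rectangular_more_queries(self, rng):
        costs = rng.normal(size=(6, 3))
        pairs = hungarian_match(costs)
        assert len(pairs) == 3
        assert sum(costs[q, t] for q, t in pairs) == pytest.approx(
            brute_force_assignment(costs))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            hungarian_match(np.array([[np.nan, 1.0], [1.0, 2.0]]))


class TestMatchCost:
    def test_perfect_prediction_limit(self):
        b = Box(0.5, 0.5, 0.2, 0.2)
        w = LossWeights()
        assert match_cost(1.0, b, b, w) == pytest.approx(-w.lambda_cls)

    def test_identical_box_dominates_disjoint(self):
        target = Box(0.5, 0.5, 0.1, 0.1)
        far = Box(0.1, 0.1, 0.1, 0.1)
        assert match_cost(0.5, target, target) < match_cost(0.5, far, target)

    def test_cost_composes_from_geometry_oracles(self):
        from gtpick.geometry import box_to_pixels, giou
        pred, target = Box(0.4, 0.5, 0.2, 0.3), Box(0.5, 0.5, 0.2, 0.2)
        w = LossWeights(2.0, 5.0, 2.0)
        l1 = abs(0.4 - 0.5) + abs(0.5 - 0.5) + abs(0.2 - 0.2) + abs(0.3 - 0.2)
        g = giou(box_to_pixels(pred, 1, 1), box_to_pixels(target, 1, 1))
        expected = 2.0 * (-0.7) + 5.0 * l1 + 2.0 * (1 - g)
        assert match_cost(0.7, pred, target, w) == pytest.approx(expected)

    def test_matrix_matches_scalar(self, rng):
        boxes = np.column_stack([rng.uniform(0.3, 0.7, 4), rng.uniform(0.3, 0.7, 4),
                                 rng.uniform(0.05, 0.2, 4), rng.uniform(0.05, 0.2, 4)])
        targets = boxes[[2, 0]] + 0.01
        scores = rng.uniform(0.1, 0.9, 4)
        mat = cost_matrix(scores, boxes, targets)
        for i in range(4):
            for j in range(2):
                expected = match_cost(scores[i], Box(*boxes[i]), Box(*targets[j]))
                assert mat[i, j] == pytest.approx(expected)


class TestGroupAssign:
    def test_counts_per_group(self, rng):
        group_of = np.repeat([0, 1], 3)
        scores = rng.uniform(0.1, 0.9, 6)
        boxes = np.column_stack([rng.uniform(0.3, 0.7, 6), rng.uniform(0.3, 0.7, 6),
                                 np.full(6, 0.1), np.full(6, 0.1)])
        targets = np.array([[0.3, 0.3, 0.1, 0.1], [0.7, 0.7, 0.1, 0.1]])
        res = group_assign(scores, boxes, targets, group_of)
        assert res.n_matched == 4
        assert len(res.pairs_by_group[0]) == 2
        assert len(res.pairs_by_group[1]) == 2
        for g, pairs in res.pairs_by_group.items():
            for q, t in pairs:
                assert group_of[q] == g
            assert len({t for _, t in pairs}) == len(pairs)

    def test_single_group_equals_plain_hungarian(self, rng):
        scores = rng.uniform(size=5)
        boxes = np.column_stack([rng.uniform(0.3, 0.7, 5), rng.uniform(0.3, 0.7, 5),
                                 np.full(5, 0.1), np.full(5, 0.1)])
        targets = np.array([[0.4, 0.4, 0.1, 0.1], [0.6, 0.6, 0.1, 0.1]])
        res = group_assign(scores, boxes, targets, np.zeros(5, dtype=int))
        direct = hungarian_match(cost_matrix(scores, boxes, targets))
        assert sorted(res.pairs_by_group[0]) == direct

    def test_empty_targets(self, rng):
        res = group_assign(rng.uniform(size=4),
                           np.full((4, 4), 0.25), np.zeros((0, 4)),
                           np.repeat([0, 1], 2))
        assert res.n_matched == 0
        assert res.all_pairs == []

    @pytest.mark.parametrize("qg,t", [(3, 2), (4, 4), (6, 5)])
    def test_matches_per_group_brute_force(self, qg, t, rng):
        group_of = np.repeat([0, 1], qg)
        scores = rng.uniform(0.05, 0.95, 2 * qg)
        boxes = np.column_stack([rng.uniform(0.2, 0.8, 2 * qg),
                                 rng.uniform(0.2, 0.8, 2 * qg),
                                 rng.uniform(0.05, 0.2, 2 * qg),
                                 rng.uniform(0.05, 0.2, 2 * qg)])
        targets = np.column_stack([rng.uniform(0.2, 0.8, t), rng.uniform(0.2, 0.8, t),
                                   rng.uniform(0.05, 0.2, t), rng.uniform(0.05, 0.2, t)])
        res = group_assign(scores, boxes, targets, group_of)
        for g in (0, 1):
            idx = np.flatnonzero(group_of == g)
            costs = cost_matrix(scores[idx], boxes[idx], targets)
            achieved = sum(costs[list(idx).index(q), t_] for q, t_ in res.pairs_by_group[g])
            assert achieved == pytest.approx(brute_force_assignment(costs))

    def test_total_positives_g_times_t(self, rng):
        """Every target claims exactly one query per group when Qg >= T."""
        group_of = np.repeat(np.arange(3), 5)
        scores = rng.uniform(size=15)
        boxes = np.column_stack([rng.uniform(0.2, 0.8, (15, 2)),
                                 rng.uniform(0.05, 0.2, (15, 2))])
        targets = np.column_stack([rng.uniform(0.2, 0.8, (4, 2)),
                                   rng.uniform(0.05, 0.2, (4, 2))])
        res = group_assign(scores, boxes, targets, group_of)
        assert res.n_matched == 3 * 4
        from collections import Counter
        counts = Counter(t for _, t in res.all_pairs)
        assert all(v == 3 for v in counts.values())


class TestFocalLoss:
    def test_perfectly_classified_contributes_nothing(self):
        loss = focal_loss(Tensor(np.array([1.0])), np.array([1.0]),
                          FocalParams(), n_matched=1)
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_scalar_evaluation_at_half(self):
        # alpha_t = 0.25, gamma = 2, p_t = 0.5 -> 0.25 * 0.25 * ln 2
        loss = focal_loss(Tensor(np.array([0.5])), np.array([1.0]),
                          FocalParams(alpha=0.25, gamma=2.0), n_matched=1)
        assert loss.item() == pytest.approx(0.25 * 0.25 * math.log(2), rel=1e-12)

    def test_gamma_zero_is_half_cross_entropy(self, rng):
        """With gamma=0, alpha=0.5 the focal loss is exactly 0.5 x BCE."""
        p = rng.uniform(0.01, 0.99, size=50)
        labels = (rng.random(50) < 0.3).astype(float)
        loss = focal_loss(Tensor(p), labels, FocalParams(alpha=0.5, gamma=0.0),
                          n_matched=7)
        bce = -(labels * np.log(p) + (1 - labels) * np.log(1 - p)).sum()
        assert loss.item() == pytest.approx(0.5 * bce / 7, abs=1e-10)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FocalParams(alpha=0.0)
        with pytest.raises(ValueError):
            FocalParams(gamma=-1.0)


class TestBoxLosses:
    def test_l1_zero_for_exact(self):
        b = np.array([[0.5, 0.5, 0.2, 0.2]])
        assert l1_box_loss(Tensor(b), b).item() == 0.0

    def test_l1_hand_value(self):
        pred = np.array([[0.5, 0.5, 0.2, 0.2]])
        tgt = np.array([[0.4, 0.5, 0.2, 0.3]])
        assert l1_box_loss(Tensor(pred), tgt).item() == pytest.approx(0.2)

    def test_l1_homogeneity(self, rng):
        tgt = np.array([[0.5, 0.5, 0.2, 0.2]])
        err = np.array([[0.02, -0.01, 0.03, 0.01]])
        one = l1_box_loss(Tensor(tgt + err), tgt).item()
        two = l1_box_loss(Tensor(tgt + 2 * err), tgt).item()
        assert two == pytest.approx(2 * one)

    def test_giou_loss_identical_boxes(self):
        b = np.array([[0.5, 0.5, 0.2, 0.2]])
        assert giou_loss(Tensor(b), b).item() == pytest.approx(0.0, abs=1e-12)

    def test_giou_loss_disjoint_hand_case(self):
        # the (0,0,1,1) vs (2,2,3,3) corner pattern scaled into unit space:
        # GIoU = -7/9, loss = 16/9
        pred = np.array([[0.05, 0.05, 0.1, 0.1]])
        tgt = np.array([[0.25, 0.25, 0.1, 0.1]])
        assert giou_loss(Tensor(pred), tgt).item() == pytest.approx(16 / 9)

    def test_giou_partial_overlap_hand_case(self):
        # (0,0,2,2) vs (1,1,3,3): GIoU = 1/7 - 2/9
        pred = np.array([[0.1, 0.1, 0.2, 0.2]])
        tgt = np.array([[0.2, 0.2, 0.2, 0.2]])
        g = float(pairwise_giou(Tensor(pred), tgt).data[0])
        assert g == pytest.approx(1 / 7 - 2 / 9)

    def test_giou_loss_range(self, rng):
        pred = np.column_stack([rng.uniform(0.2, 0.8, (1000, 2)),
                                rng.uniform(0.01, 0.3, (1000, 2))])
        tgt = np.column_stack([rng.uniform(0.2, 0.8, (1000, 2)),
                               rng.uniform(0.01, 0.3, (1000, 2))])
        per_pair = 1.0 - pairwise_giou(Tensor(pred), tgt).data
        assert np.all((per_pair >= 0.0) & (per_pair <= 2.0))

    def test_empty_matches_contribute_zero(self):
        assert l1_box_loss(Tensor(np.zeros((0, 4))), np.zeros((0, 4))).item() == 0.0
        assert giou_loss(Tensor(np.zeros((0, 4))), np.zeros((0, 4))).item() == 0.0


class TestTotalLoss:
    def test_weighted_sum_hand_value(self):
        assert total_loss(0.1, 0.2, 0.3, LossWeights(2, 5, 2)) == pytest.approx(1.8)

    def test_zeroed_weights_leave_single_term(self):
        assert total_loss(0.7, 0.9, 1.1, LossWeights(0, 5, 0)) == pytest.approx(4.5)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            LossWeights(-1, 0, 0)
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0)

    def test_gradient_matches_finite_differences(self):
        """d L_total / d(box coord) agrees with central differences at h=1e-5."""
        weights = LossWeights(2.0, 5.0, 2.0)
        tgt = np.array([[0.45, 0.55, 0.2, 0.2], [0.3, 0.3, 0.15, 0.15]])

        def compute(raw):
            boxes = Tensor(raw, requires_grad=True)
            scores = Tensor(np.array([0.8, 0.6]), requires_grad=True)
            l_cls = focal_loss(scores, np.ones(2), FocalParams(), n_matched=2)
            total = total_loss(l_cls, l1_box_loss(boxes, tgt),
                               giou_loss(boxes, tgt), weights)
            return boxes, total

        raw = np.array([[0.5, 0.5, 0.22, 0.18], [0.35, 0.28, 0.12, 0.2]])
        boxes, total = compute(raw.copy())
        total.backward()
        h = 1e-5
        for idx in [(0, 0), (0, 2), (1, 1), (1, 3)]:
            plus, minus = raw.copy(), raw.copy()
            plus[idx] += h
            minus[idx] -= h
            fd = (compute(plus)[1].item() - compute(minus)[1].item()) / (2 * h)
            assert boxes.grad[idx] == pytest.approx(fd, rel=1e-4)


class TestDetectionLoss:
    def test_breakdown_is_exact_weighted_sum(self, rng):
        scores = Tensor(rng.uniform(0.1, 0.9, size=(6, 2)))
        boxes = Tensor(np.stack([np.column_stack(
            [rng.uniform(0.3, 0.7, (6, 2)), rng.uniform(0.05, 0.2, (6, 2))])
            for _ in range(2)], axis=1))
        targets = [np.array([[0.4, 0.4, 0.1, 0.1]]),
                   np.array([[0.6, 0.6, 0.1, 0.1], [0.3, 0.7, 0.1, 0.1]])]
        w = LossWeights(2.0, 5.0, 2.0)
        total, bd = detection_loss(scores, boxes, targets, np.repeat([0, 1], 3), w)
        assert bd.l_total == pytest.approx(
            w.lambda_cls * bd.l_cls + w.lambda_l1 * bd.l_l1 + w.lambda_giou * bd.l_giou)
        assert total.item() == pytest.approx(bd.l_total)
        assert bd.n_matched == 2 * 3  # one pair per target per group

    def test_gradient_descent_reduces_loss_on_toy_batch(self, rng):
        """A fixed toy batch is optimizable: 50 steps shrink the total loss."""
        targets = [np.array([[0.35, 0.4, 0.15, 0.15], [0.7, 0.65, 0.12, 0.12]])]
        group_of = np.repeat([0, 1], 3)
        raw_scores = nn.Parameter(rng.normal(size=(6, 1)))
        raw_boxes = nn.Parameter(rng.normal(size=(6, 1, 4)) * 0.3)
        opt = nn.AdamW([raw_scores, raw_boxes], lr=0.05, weight_decay=0.0)
        history = []
        for _ in range(50):
            total, _ = detection_loss(raw_scores.sigmoid(), raw_boxes.sigmoid(),
                                      targets, group_of)
            opt.zero_grad()
            total.backward()
            opt.step()
            history.append(total.item())
        assert history[-1] < 0.3 * history[0]
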