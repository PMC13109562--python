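import numpy as np
import pytest

from denseleaf.assign import (Assignment, CostMatrix, CostWeights, MatchConfig,
                              build_cost_matrix, combined_loss, cqr_compose,
                              hungarian_match, topk_hungarian_match)
from denseleaf.boxes import BoundingBox, ScoredBox, box_giou
from .conftest import random_box, random_scored
from .oracles import hungarian_oracle, topk_rounds_oracle


class TestCostMatrix:
    def test_exact_match_has_zero_cost(self):
        box = np.array([[0.5, 0.5, 0.2, 0.2]])
        cost = build_cost_matrix(box, np.array([1.0]), box)
        assert cost.values[0, 0] == pytest.approx(0.0)

    def test_empty_ground_truth_gives_zero_columns(self):
        cost = build_cost_matrix(np.array([[0.5, 0.5, 0.2, 0.2]]),
                                 np.array([0.7]), np.zeros((0, 4)))
        assert cost.values.shape == (1, 0)
        assert hungarian_match(cost).pairs == []

    def test_matches_hand_computed_terms(self):
        # one prediction vs one gt, every term recomputed in straight-line form
        pred = np.array([[0.5, 0.5, 0.4, 0.4]])
        gt = np.array([[0.6, 0.5, 0.2, 0.4]])
        prob = 0.3
        w = CostWeights(w_cls=2.0, w_l1=5.0, w_giou=2.0)
        cost = build_cost_matrix(pred, np.array([prob]), gt, w)
        l1 = abs(0.5 - 0.6) + abs(0.4 - 0.2)
        g = box_giou(BoundingBox(0.3, 0.3, 0.7, 0.7), BoundingBox(0.5, 0.3, 0.7, 0.7))
        expected = 2.0 * (1 - prob) + 5.0 * l1 + 2.0 * (1 - g)
        assert cost.values[0, 0] == pytest.approx(expected)

    def test_higher_class_probability_never_raises_cost(self, rng):
        pred = rng.uniform(0.2, 0.8, (5, 4))
        gt = rng.uniform(0.2, 0.8, (3, 4))
        lo = build_cost_matrix(pred, np.full(5, 0.2), gt).values
        hi = build_cost_matrix(pred, np.full(5, 0.9), gt).values
        assert np.all(hi <= lo + 1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_cost_matrix(np.zeros((2, 4)), np.zeros(3), np.zeros((1, 4)))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            CostMatrix(np.array([[np.inf]]))


class TestHungarian:
    @pytest.mark.parametrize("values, pairs, total", [
        ([[3.5]], [(0, 0)], 3.5),
        ([[1, 2], [2, 1]], [(0, 0), (1, 1)], 2.0),
        ([[0.5], [0.2]], [(1, 0)], 0.2),
    ])
    def test_examples(self, values, pairs, total):
        a = hungarian_match(CostMatrix(np.array(values, dtype=float)))
        assert a.pairs == pairs
        assert a.total_cost == pytest.approx(total)

    def test_matches_bruteforce_minimum(self, rng):
        for _ in range(200):
            p = int(rng.integers(1, 7))
            g = int(rng.integers(1, 7))
            cost = rng.uniform(0, 10, (p, g))
            ours = hungarian_match(CostMatrix(cost))
            _, best = hungarian_oracle(cost)
            assert ours.total_cost == pytest.approx(best)
            assert len(ours.pairs) == min(p, g)
            assert len(set(ours.prediction_indices())) == len(ours.pairs)
            assert len(set(ours.ground_truth_indices())) == len(ours.pairs)


class TestTopKHungarian:
    def test_k1_reduces_to_hungarian(self, rng):
        for _ in range(20):
            cost = CostMatrix(rng.uniform(0, 5, (6, 3)))
            assert topk_hungarian_match(cost, 1).pairs == hungarian_match(cost).pairs

    def test_single_gt_two_rounds(self):
        cost = CostMatrix(np.array([[0.3], [0.1], [0.2]]))
        a = topk_hungarian_match(cost, 2)
        assert a.pairs == [(1, 0), (2, 0)]
        assert a.total_cost == pytest.approx(0.3)

    def test_pool_exhaustion(self):
        cost = CostMatrix(np.array([[0.3], [0.1], [0.2]]))
        assert len(topk_hungarian_match(cost, 4).pairs) == 3

    def test_matches_sequential_rounds_oracle(self, rng):
        for _ in range(60):
            p = int(rng.integers(1, 13))
            g = int(rng.integers(1, 5))
            k = int(rng.integers(1, 5))
            cost = rng.uniform(0, 10, (p, g))
            ours = topk_hungarian_match(CostMatrix(cost), k)
            assert ours.pairs == topk_rounds_oracle(cost, k)
            # count law and multiplicity bounds
            assert len(ours.pairs) == min(k * g, p)
            assert len(set(ours.prediction_indices())) == len(ours.pairs)
            gt_counts = np.bincount(ours.ground_truth_indices(), minlength=g)
            assert gt_counts.max(initial=0) <= k

    def test_enlarging_pool_never_raises_cost(self, rng):
        # with predictions >= ground truths, extra candidates can only help
        for _ in range(30):
            g = int(rng.integers(1, 4))
            p = int(rng.integers(g, 8))
            cost = rng.uniform(0, 10, (p, g))
            extra = rng.uniform(0, 10, (2, g))
            small = hungarian_match(CostMatrix(cost)).total_cost
            large = hungarian_match(CostMatrix(np.vstack([cost, extra]))).total_cost
            assert large <= small + 1e-12

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            topk_hungarian_match(CostMatrix(np.ones((2, 1))), 0)


class TestCQRCompose:
    SIZE = (100.0, 100.0)

    def test_no_extras_reduces_to_plain_hungarian(self, rng):
        gts = [random_box(rng) for _ in range(3)]
        # originals pairwise disjoint so NMS culls nothing
        originals = [ScoredBox(BoundingBox(i * 25.0, 0, i * 25.0 + 20, 20), 0.5 + 0.1 * i)
                     for i in range(4)]
        cfg = MatchConfig(k=4, nms_threshold=0.7)
        a_ori, a_extra = cqr_compose(originals, [], gts, cfg, self.SIZE)
        boxes = np.stack([np.array([(b.box.x_min + b.box.x_max) / 200,
                                    (b.box.y_min + b.box.y_max) / 200,
                                    b.box.width / 100, b.box.height / 100])
                          for b in originals])
        probs = np.array([b.score for b in originals])
        gt_arr = np.stack([np.array([(g.x_min + g.x_max) / 200, (g.y_min + g.y_max) / 200,
                                     g.width / 100, g.height / 100]) for g in gts])
        direct = hungarian_match(build_cost_matrix(boxes, probs, gt_arr, cfg.weights))
        assert a_ori.pairs == direct.pairs
        assert a_extra.pairs == []

    def test_duplicate_original_culled_before_matching(self):
        gt = [BoundingBox(10, 10, 30, 30)]
        dup = BoundingBox(11, 11, 31, 31)
        originals = [ScoredBox(dup, 0.9), ScoredBox(dup, 0.6)]
        cfg = MatchConfig(nms_threshold=0.7)
        a_ori, _ = cqr_compose(originals, [], gt, cfg, self.SIZE)
        # the lower-scored duplicate never reaches the matcher
        assert a_ori.pairs == [(0, 0)]

    def test_extra_branch_count_law(self, rng):
        gts = [random_box(rng) for _ in range(2)]
        extras = random_scored(rng, 8)
        a_ori, a_extra = cqr_compose([], extras, gts, MatchConfig(k=4), self.SIZE)
        assert a_ori.pairs == []
        assert len(a_extra.pairs) == min(4 * 2, 8)

    def test_extras_ranked_by_score_not_position(self):
        gt = [BoundingBox(10, 10, 30, 30)]
        near = BoundingBox(10, 10, 30, 30)
        far = BoundingBox(60, 60, 90, 90)
        extras = [ScoredBox(far, 0.9), ScoredBox(near, 0.1)]
        _, a_extra = cqr_compose([], extras, gt, MatchConfig(k=1), self.SIZE)
        # sorting reorders candidates but matching still picks the best box
        assert a_extra.pairs == [(1, 0)]


@pytest.mark.parametrize("ori, extra, lam, expected", [
    (2.0, 1.0, 0.5, 2.5),
    (2.0, 5.0, 0.0, 2.0),
    (3.0, 0.0, 0.7, 3.0),
])
def test_combined_loss(ori, extra, lam, expected):
    assert combined_loss(ori, extra, lam) == pytest.approx(expected)


def test_combined_loss_rejects_negative_weight():
    with pytest.raises(ValueError):
        combined_loss(1.0, 1.0, -0.1)
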