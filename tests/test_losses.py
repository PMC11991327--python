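"""Loss closed forms, brute-force oracles, assignment behaviour."""

import numpy as np
import pytest

from citrusdet.nn import Tensor
from citrusdet.losses import (ciou_loss, dfl_loss, dfl_loss_logits, cls_loss,
                              bce_with_logits, total_loss, LossWeights, assign_targets,
                              DetectionLoss)
from citrusdet.heads import make_anchors


def _ciou_reference(p, g):
    """Independent scalar evaluation of the complete-IoU formula."""
    px1, py1, px2, py2 = p
    gx1, gy1, gx2, gy2 = g
    iw = max(0.0, min(px2, gx2) - max(px1, gx1))
    ih = max(0.0, min(py2, gy2) - max(py1, gy1))
    inter = iw * ih
    union = (px2 - px1) * (py2 - py1) + (gx2 - gx1) * (gy2 - gy1) - inter
    iou = inter / union
    cw = max(px2, gx2) - min(px1, gx1)
    ch = max(py2, gy2) - min(py1, gy1)
    rho2 = ((px1 + px2 - gx1 - gx2) / 2) ** 2 + ((py1 + py2 - gy1 - gy2) / 2) ** 2
    v = 4 / np.pi ** 2 * (np.arctan((gx2 - gx1) / (gy2 - gy1))
                          - np.arctan((px2 - px1) / (py2 - py1))) ** 2
    alpha = v / (1 - iou + v) if (1 - iou + v) > 0 else 0.0
    return 1 - iou + rho2 / (cw ** 2 + ch ** 2) + alpha * v


class TestCiou:
    def test_identical_boxes_zero(self):
        assert ciou_loss((0, 0, 2, 1), (0, 0, 2, 1)) < 1e-6

    def test_equal_aspect_ratio_drops_v_term(self):
        # same aspect ratio, shifted: loss = 1 - IoU + rho2/c2 exactly
        p, g = (0, 0, 2, 1), (4, 0, 6, 1)
        got = ciou_loss(p, g)
        want = 1.0 + ((5 - 1) ** 2) / (6 ** 2 + 1 ** 2)
        assert abs(got - want) < 1e-6

    def test_hand_worked_disjoint_case(self):
        # IoU=0, rho2=8, c2=18, v=0 -> 1 + 8/18
        assert abs(ciou_loss((0, 0, 1, 1), (2, 2, 3, 3)) - (1 + 8 / 18)) < 1e-6

    def test_thousand_random_instances_match_reference(self, rng):
        for _ in range(1000):
            p = rng.random(4) * 10
            p[2:] = p[:2] + rng.random(2) * 10 + 0.1
            g = rng.random(4) * 10
            g[2:] = g[:2] + rng.random(2) * 10 + 0.1
            assert abs(ciou_loss(tuple(p), tuple(g)) - _ciou_reference(p, g)) < 1e-5

    def test_range_and_translation_invariance(self, rng):
        for _ in range(200):
            p = rng.random(4) * 10
            p[2:] = p[:2] + rng.random(2) * 5 + 0.1
            g = rng.random(4) * 10
            g[2:] = g[:2] + rng.random(2) * 5 + 0.1
            val = ciou_loss(tuple(p), tuple(g))
            assert 0.0 <= val < 3.0
            t = rng.random(2) * 100
            shift = np.array([t[0], t[1], t[0], t[1]])
            assert abs(ciou_loss(tuple(p + shift), tuple(g + shift)) - val) < 1e-6

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            ciou_loss((0, 0, 0, 1), (0, 0, 1, 1))


class TestDfl:
    def test_perfect_one_sided_prediction(self):
        assert dfl_loss(1.0, 1e-9, 3.0, 3) == 0.0

    def test_midpoint_equal_bins_is_ln2(self):
        assert abs(dfl_loss(0.5, 0.5, 4.5, 4) - np.log(2)) < 1e-12

    def test_thousand_random_instances_match_direct_formula(self, rng):
        for _ in range(1000):
            yi = rng.integers(0, 14)
            y = yi + rng.random()
            si = rng.random() * 0.98 + 0.01
            sip = rng.random() * 0.98 + 0.01
            want = -((yi + 1 - y) * np.log(si) + (y - yi) * np.log(sip))
            assert abs(dfl_loss(si, sip, y, yi) - want) < 1e-9

    def test_out_of_bracket_target_rejected(self):
        with pytest.raises(ValueError):
            dfl_loss(0.5, 0.5, 5.5, 3)

    def test_minimized_at_linear_interpolation_weight(self):
        # over S_i + S_{i+1} = 1, the grid minimum sits at S_i = y_{i+1} - y
        y, yi = 4.3, 4
        grid = np.linspace(0.01, 0.99, 981)
        losses = [dfl_loss(s, 1 - s, y, yi) for s in grid]
        best = grid[int(np.argmin(losses))]
        assert abs(best - (yi + 1 - y)) < 5e-3

    def test_logit_form_matches_probability_form(self, rng):
        logits = rng.standard_normal((5, 4, 16))
        t = rng.random((5, 4)) * 14.9
        got = dfl_loss_logits(Tensor(logits), t).data
        e = np.exp(logits - logits.max(-1, keepdims=True))
        p = e / e.sum(-1, keepdims=True)
        tl = np.floor(t).astype(int)
        i0, i1 = np.indices(t.shape)
        want = -((tl + 1 - t) * np.log(p[i0, i1, tl]) + (t - tl) * np.log(p[i0, i1, tl + 1]))
        np.testing.assert_allclose(got, want, atol=1e-6)


class TestCls:
    def test_zero_logits_give_ln2(self):
        assert abs(cls_loss(np.zeros((4, 6)), np.zeros((4, 6))) - np.log(2)) < 1e-12

    def test_saturated_correct_prediction_vanishes(self):
        assert cls_loss(np.full((2, 6), 40.0), np.ones((2, 6))) < 1e-12

    def test_thousand_random_instances_match_naive_form(self, rng):
        x = rng.standard_normal(1000) * 4
        y = rng.integers(0, 2, 1000).astype(float)
        naive = -(y * np.log(1 / (1 + np.exp(-x))) + (1 - y) * np.log(1 - 1 / (1 + np.exp(-x))))
        got = bce_with_logits(x, y)
        np.testing.assert_allclose(got, naive, atol=1e-7)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            cls_loss(np.zeros((2, 6)), np.full((2, 6), 0.5))


class TestTotal:
    def test_published_weights(self):
        assert total_loss(1.0, 1.0, 1.0) == 7.5 + 1.5 + 0.5

    def test_zero_components(self):
        assert total_loss(0.0, 0.0, 0.0) == 0.0

    def test_linearity_per_component(self):
        base = total_loss(1.0, 1.0, 1.0)
        assert total_loss(2.0, 1.0, 1.0) - base == 7.5

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(box_weight=-1.0)


class TestAssignment:
    def _setup(self, size=32):
        shapes = [(size // s, size // s) for s in (8, 16, 32)]
        centers, strides = make_anchors(shapes, (8, 16, 32))
        return centers, strides

    def test_single_gt_gets_covering_anchor(self, rng):
        centers, _ = self._setup()
        A = len(centers)
        scores = np.full((A, 6), 0.5)
        boxes = np.concatenate([centers - 4, centers + 4], axis=1)
        gt = np.array([[2.0, 2.0, 14.0, 14.0]])
        fg, gidx, tsc = assign_targets(scores, boxes, centers, gt, [0])
        assert fg.any()
        assert (gidx[fg] == 0).all()

    def test_no_gts_empty_assignment(self):
        centers, _ = self._setup()
        fg, gidx, tsc = assign_targets(np.zeros((len(centers), 6)),
                                       np.zeros((len(centers), 4)), centers, [], [])
        assert not fg.any() and tsc.sum() == 0

    def test_disjoint_gts_no_double_assignment(self, rng):
        centers, _ = self._setup()
        A = len(centers)
        scores = np.full((A, 6), 0.5)
        boxes = np.concatenate([centers - 4, centers + 4], axis=1)
        gts = np.array([[0.0, 0.0, 12.0, 12.0], [20.0, 20.0, 32.0, 32.0]])
        fg, gidx, _ = assign_targets(scores, boxes, centers, gts, [0, 1], topk=1)
        # enumerate: each assigned anchor belongs to exactly one gt, and its
        # centre lies inside that gt
        for a in np.flatnonzero(fg):
            g = gidx[a]
            assert gts[g, 0] < centers[a, 0] < gts[g, 2]
            assert gts[g, 1] < centers[a, 1] < gts[g, 3]

    def test_one_gradient_step_reduces_loss(self, rng):
        from citrusdet.model import build_model
        from citrusdet.train import Adam

        model = build_model("v8n-DE", nc=6, seed=0).train()
        crit = DetectionLoss(6)
        x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        targets = [(np.array([[8.0, 8.0, 40.0, 40.0]]), np.array([2]))]
        opt = Adam(model.parameters(), 0.01)
        out = model(Tensor(x))
        loss0, _ = crit(out, targets)
        opt.zero_grad()
        loss0.backward()
        opt.step()
        out = model(Tensor(x))
        loss1, _ = crit(out, targets)
        assert float(loss1.data) < float(loss0.data)
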