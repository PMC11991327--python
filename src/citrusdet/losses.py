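"""Composite detection loss: CIoU box loss, distribution focal loss,
binary cross-entropy classification loss, and task-aligned assignment.

Total = box_weight * CIoU + dfl_weight * DFL + cls_weight * Cls with the
published weights 7.5 / 1.5 / 0.5.  Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor
from .nn.tensor import _sigmoid
from .heads import box_iou, dfl_expectation, make_anchors

__all__ = ["LossWeights", "ciou_loss", "dfl_loss", "dfl_loss_logits", "cls_loss",
           "bce_with_logits", "total_loss", "assign_targets", "DetectionLoss"]

EPS = 1e-7


@dataclass
class LossWeights:
    box_weight: float = 7.5
    dfl_weight: float = 1.5
    cls_weight: float = 0.5

    def __post_init__(self):
        if min(self.box_weight, self.dfl_weight, self.cls_weight) < 0:
            raise ValueError("loss weights must be nonnegative")


def _is_tensor(*xs):
    return any(isinstance(x, Tensor) for x in xs)


def ciou_loss(pred, gt, reduce=None):
    """Complete-IoU loss: 1 - IoU + rho^2/c^2 + alpha*v  (xyxy boxes).

    Works elementwise on (..., 4) arrays or autograd Tensors; the aspect
    weight alpha is treated as a constant, the standard practice.
    """
    tensor_mode = _is_tensor(pred, gt)
    p = pred if tensor_mode else np.asarray(pred, dtype=np.float64)
    g = gt if tensor_mode else np.asarray(gt, dtype=np.float64)
    pd, gd = (p.data if isinstance(p, Tensor) else p), (g.data if isinstance(g, Tensor) else g)
    if np.any(pd[..., 2] - pd[..., 0] <= 0) or np.any(pd[..., 3] - pd[..., 1] <= 0) \
            or np.any(gd[..., 2] - gd[..., 0] <= 0) or np.any(gd[..., 3] - gd[..., 1] <= 0):
        raise ValueError("degenerate (zero-area) box passed to ciou_loss")
    p, g = as_tensor(p), as_tensor(g)

    px1, py1, px2, py2 = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    gx1, gy1, gx2, gy2 = g[..., 0], g[..., 1], g[..., 2], g[..., 3]
    pw, ph = px2 - px1, py2 - py1
    gw, gh = gx2 - gx1, gy2 - gy1

    inter_w = px2.minimum(gx2) - px1.maximum(gx1)
    inter_h = py2.minimum(gy2) - py1.maximum(gy1)
    inter = inter_w.clamp_min(0.0) * inter_h.clamp_min(0.0)
    union = pw * ph + gw * gh - inter
    iou = inter / (union + EPS)

    cw = px2.maximum(gx2) - px1.minimum(gx1)
    chh = py2.maximum(gy2) - py1.minimum(gy1)
    c2 = cw * cw + chh * chh + EPS
    dx = (px1 + px2) * 0.5 - (gx1 + gx2) * 0.5
    dy = (py1 + py2) * 0.5 - (gy1 + gy2) * 0.5
    rho2 = dx * dx + dy * dy

    datan = (gw / gh).arctan() - (pw / ph).arctan()
    v = (4.0 / np.pi ** 2) * (datan * datan)
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + EPS))  # constant weight
    loss = 1.0 - iou + rho2 / c2 + alpha * v
    if not tensor_mode:
        loss = loss.data
        return float(loss) if np.ndim(loss) == 0 else loss
    return loss


def dfl_loss(s_i, s_ip1, y, y_i):
    """Distribution focal loss from the two bracketing-bin probabilities.

    -[(y_{i+1}-y) log S_i + (y-y_i) log S_{i+1}]  with y_{i+1} = y_i + 1.
    """
    s_i, s_ip1, y, y_i = (np.asarray(v, dtype=np.float64) for v in (s_i, s_ip1, y, y_i))
    if np.any(y < y_i) or np.any(y > y_i + 1):
        raise ValueError("target y must lie within [y_i, y_i + 1]")
    s_i = np.clip(s_i, EPS, None)
    s_ip1 = np.clip(s_ip1, EPS, None)
    out = -((y_i + 1 - y) * np.log(s_i) + (y - y_i) * np.log(s_ip1))
    return float(out) if np.ndim(out) == 0 else out


def dfl_loss_logits(logits: Tensor, target):
    """DFL on raw bin logits (..., reg_max) against continuous targets."""
    t = np.asarray(target, dtype=np.float64)
    tl = np.floor(t).astype(int)
    wl = (tl + 1 - t).astype(np.float32)
    wr = (t - tl).astype(np.float32)
    p = logits.softmax(axis=-1).clamp_min(EPS).log()
    idx = np.indices(t.shape)
    left = p[(*idx, tl)]
    right = p[(*idx, np.minimum(tl + 1, logits.shape[-1] - 1))]
    return -(left * Tensor(wl) + right * Tensor(wr))


def bce_with_logits(logits, targets):
    """Numerically stable elementwise binary cross entropy on logits."""
    if isinstance(logits, Tensor):
        x = logits
        y = as_tensor(np.asarray(targets, dtype=np.float32))
        # max(x,0) - x*y + log(1 + exp(-|x|))
        return x.maximum(0.0) - x * y + ((-x.abs()).exp() + 1.0).log()
    x = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    return np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))


def cls_loss(logits, labels):
    """Mean BCE-with-logits over samples x categories (binary labels)."""
    lab = np.asarray(labels)
    if not np.all((lab == 0) | (lab == 1)):
        raise ValueError("labels must be binary")
    out = bce_with_logits(logits, lab)
    return out.mean() if isinstance(out, Tensor) else float(out.mean())


def total_loss(box, dfl, cls, weights: LossWeights = LossWeights()):
    return weights.box_weight * box + weights.dfl_weight * dfl + weights.cls_weight * cls


# ------------------------------------------------------------- assignment
def assign_targets(pred_scores, pred_boxes, anchor_points, gt_boxes, gt_labels,
                   topk=10, alpha=0.5, beta=6.0):
    """Task-aligned one-stage assignment (single image).

    metric = score^alpha * IoU^beta over anchors whose centre lies inside
    the box; top-k anchors per ground truth; anchors claimed by several
    ground truths go to the one with the highest metric.

    Returns (fg_mask (A,), gt_idx (A,), target_scores (A,)).
    """
    A = len(anchor_points)
    fg = np.zeros(A, dtype=bool)
    gt_idx = np.full(A, -1, dtype=int)
    tsc = np.zeros(A)
    if len(gt_boxes) == 0:
        return fg, gt_idx, tsc
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64)
    inside = (
        (anchor_points[:, 0][:, None] > gt_boxes[None, :, 0])
        & (anchor_points[:, 0][:, None] < gt_boxes[None, :, 2])
        & (anchor_points[:, 1][:, None] > gt_boxes[None, :, 1])
        & (anchor_points[:, 1][:, None] < gt_boxes[None, :, 3])
    )                                                   # (A, G)
    iou = box_iou(pred_boxes, gt_boxes)                 # (A, G)
    score_for_gt = pred_scores[:, np.asarray(gt_labels, dtype=int)]   # (A, G)
    metric = np.clip(score_for_gt, EPS, None) ** alpha * np.clip(iou, 0, None) ** beta
    metric = np.where(inside, metric, 0.0)

    cand = np.zeros_like(inside)
    G = gt_boxes.shape[0]
    for g in range(G):
        valid = np.flatnonzero(inside[:, g])
        if valid.size == 0:
            continue
        order = valid[np.argsort(-metric[valid, g], kind="stable")][:topk]
        cand[order, g] = True
    # conflicts: anchor keeps the gt with the largest metric
    claimed = cand.sum(axis=1)
    for a in np.flatnonzero(claimed > 1):
        best = np.argmax(metric[a] * cand[a])
        cand[a] = False
        cand[a, best] = True
    for g in range(G):
        anchors = np.flatnonzero(cand[:, g])
        if anchors.size == 0:
            continue
        m = metric[anchors, g]
        norm = m / (m.max() + EPS) * max(iou[anchors, g].max(), EPS)
        fg[anchors] = True
        gt_idx[anchors] = g
        tsc[anchors] = norm
    return fg, gt_idx, tsc


class DetectionLoss:
    """Training criterion wiring assignment + the three loss terms."""

    def __init__(self, nc, reg_max=16, strides=(8, 16, 32), weights: LossWeights = LossWeights(),
                 topk=10, alpha=0.5, beta=6.0):
        self.nc, self.reg_max, self.strides = nc, reg_max, strides
        self.weights = weights
        self.topk, self.alpha, self.beta = topk, alpha, beta

    def _flatten(self, head_out):
        regs, clss = [], []
        for r, c in head_out:
            B, _, H, W = r.shape
            regs.append(r.reshape(B, 4, self.reg_max, H * W).transpose(0, 3, 1, 2))
            clss.append(c.reshape(B, self.nc, H * W).transpose(0, 2, 1))
        from .nn import concat

        return concat(regs, axis=1), concat(clss, axis=1)  # (B,A,4,rm), (B,A,nc)

    def __call__(self, head_out, targets):
        """targets: list per image of (boxes_xyxy_pixels (G,4), labels (G,))."""
        shapes = [r.shape[2:] for r, _ in head_out]
        centers, strs = make_anchors(shapes, self.strides)
        reg, cls = self._flatten(head_out)
        B, A = cls.shape[0], cls.shape[1]

        # decoded boxes (pixels), differentiable
        ltrb = dfl_expectation(reg, self.reg_max)          # (B,A,4) Tensor
        ltrb_px = ltrb * Tensor(strs[None, :, None].astype(np.float32))
        cen = Tensor(centers[None].astype(np.float32))
        x1y1 = cen - ltrb_px[..., :2]
        x2y2 = cen + ltrb_px[..., 2:]
        from .nn import concat as _cat

        boxes = _cat([x1y1, x2y2], axis=2)                 # (B,A,4)

        pred_scores = _sigmoid(cls.data)
        box_terms, dfl_terms, n_fg = [], [], 0
        cls_target = np.zeros((B, A, self.nc), dtype=np.float32)
        score_sum = 0.0
        for b in range(B):
            gt_boxes, gt_labels = targets[b]
            fg, gidx, tsc = assign_targets(pred_scores[b], boxes.data[b], centers,
                                           gt_boxes, gt_labels,
                                           self.topk, self.alpha, self.beta)
            idx = np.flatnonzero(fg)
            if idx.size:
                gi = gidx[idx]
                gboxes = np.asarray(gt_boxes, dtype=np.float64)[gi]
                w = Tensor(tsc[idx].astype(np.float32))
                pb = boxes[b][idx]
                ci = ciou_loss(pb, Tensor(gboxes.astype(np.float32)))
                box_terms.append((ci * w).sum())
                # DFL targets in stride units, clipped to the bin range
                s = strs[idx][:, None]
                cxy = centers[idx]
                lt = np.concatenate([cxy - gboxes[:, :2], gboxes[:, 2:] - cxy], axis=1) / s
                lt = np.clip(lt, 0, self.reg_max - 1 - 0.01)
                dterm = dfl_loss_logits(reg[b][idx], lt).mean(axis=-1)
                dfl_terms.append((dterm * w).sum())
                # binary targets per the BCE formulation: assigned anchor-class = 1
                cls_target[b, idx, np.asarray(gt_labels, dtype=int)[gi]] = 1.0
                n_fg += idx.size
                score_sum += tsc[idx].sum()
        score_sum = max(score_sum, EPS)
        cls_l = bce_with_logits(cls, cls_target).sum() * (1.0 / max(n_fg, 1))
        if box_terms:
            # weighted average over assigned anchors
            box_l = sum(box_terms[1:], box_terms[0]) * (1.0 / score_sum)
            dfl_l = sum(dfl_terms[1:], dfl_terms[0]) * (1.0 / score_sum)
        else:
            box_l = Tensor(np.float32(0.0))
            dfl_l = Tensor(np.float32(0.0))
        tot = total_loss(box_l, dfl_l, cls_l, self.weights)
        parts = {"box": float(box_l.data), "dfl": float(dfl_l.data),
                 "cls": float(cls_l.data), "total": float(tot.data), "n_fg": n_fg}
        return tot, parts
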