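"""Detection heads: decoupled baseline and the shared-parameter head.

Both heads emit, per scale (strides 8/16/32), a box-distribution map with
``4*reg_max`` channels and a class-logit map with ``nc`` channels — the
interchangeable HeadOutput signature.

Three head designs exist in this model family.  The *coupled* head (one
conv tower emitting class and box outputs jointly, YOLOv5-style) trades
accuracy for size and is superseded by the other two; it is described here
for reference only and not implemented.  The *decoupled* head gives each
task its own pair of 3x3 convs per scale — accurate but heavy.

``DetectShared`` merges the computation the decoupled head duplicates:
each scale runs one shared stem — a partial convolution (3x3 over a 1/4
channel slice, the rest passed through untouched) followed by a 1x1
channel-fusion conv — and the classification and regression tasks then
branch into single 1x1 prediction convs.  A per-scale learned scale factor
sits on the regression output so one set of box-prediction weights can
serve all three strides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, Param, Conv, Conv2d, concat
from .nn.tensor import _sigmoid as _sig

__all__ = [
    "Detection", "PartialConv", "DecoupledHead", "DetectShared",
    "dfl_expectation", "make_anchors", "decode_boxes", "postprocess", "nms",
]


@dataclass
class Detection:
    image_id: int
    class_id: int
    box: tuple  # (x1, y1, x2, y2) pixels
    confidence: float

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence out of range: {self.confidence}")


class PartialConv(Module):
    """Convolve the first ``ceil(ratio*C)`` channels, pass the rest through.

    The untouched channels are returned bit-identical to the input.
    """

    def __init__(self, c, ratio=0.25, k=3, rng=None):
        super().__init__()
        n = c * ratio
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"ratio {ratio} does not split {c} channels integrally")
        self.c, self.nconv = c, int(round(n))
        self.conv = Conv2d(self.nconv, self.nconv, k, 1, bias=False, rng=rng)

    def forward(self, x):
        if self.nconv == self.c:
            return self.conv(x)
        head, tail = x[:, : self.nconv], x[:, self.nconv:]
        return concat([self.conv(head), tail], axis=1)


def _dfl_proj(reg_max):
    return np.arange(reg_max, dtype=np.float32)


def _init_pred_biases(reg_conv, cls_conv, prior=0.01):
    """Start box offsets near one stride-unit and class scores at a low prior."""
    reg_conv.bias.data[:] = 1.0
    cls_conv.bias.data[:] = np.log(prior / (1.0 - prior))


class DecoupledHead(Module):
    """Baseline two-tower head: unshared 3x3 convs per task per scale."""

    def __init__(self, nc=6, ch=(64, 128, 256), reg_max=16, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.nc, self.ch, self.reg_max = nc, tuple(ch), reg_max
        self.strides = (8, 16, 32)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.reg_towers, self.cls_towers = [], []
        for c in ch:
            self.reg_towers.append([Conv(c, c2, 3, rng=rng), Conv(c2, c2, 3, rng=rng),
                                    Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng)])
            self.cls_towers.append([Conv(c, c3, 3, rng=rng), Conv(c3, c3, 3, rng=rng),
                                    Conv2d(c3, nc, 1, bias=True, rng=rng)])
            _init_pred_biases(self.reg_towers[-1][-1], self.cls_towers[-1][-1])
        self.dfl_proj = Param(_dfl_proj(reg_max))
        self.dfl_proj.frozen = True

    def forward(self, feats):
        if len(feats) != len(self.ch):
            raise ValueError(f"expected {len(self.ch)} scales, got {len(feats)}")
        out = []
        for x, rt, ct in zip(feats, self.reg_towers, self.cls_towers):
            r = x
            for m in rt:
                r = m(r)
            c = x
            for m in ct:
                c = m(c)
            out.append((r, c))
        return out


class DetectShared(Module):
    """Shared-parameter head: one stem per scale feeds both task branches."""

    def __init__(self, nc=6, ch=(64, 128, 256), reg_max=16, ratio=0.25, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.nc, self.ch, self.reg_max = nc, tuple(ch), reg_max
        self.strides = (8, 16, 32)
        self.pconvs = [PartialConv(c, ratio, 3, rng=rng) for c in ch]
        self.fuses = [Conv2d(c, c, 1, bias=True, rng=rng) for c in ch]
        self.regs = [Conv2d(c, 4 * reg_max, 1, bias=True, rng=rng) for c in ch]
        self.clss = [Conv2d(c, nc, 1, bias=True, rng=rng) for c in ch]
        self.scales = [Param(np.ones(1, dtype=np.float32)) for _ in ch]
        for rg, cl in zip(self.regs, self.clss):
            _init_pred_biases(rg, cl)
        self.dfl_proj = Param(_dfl_proj(reg_max))
        self.dfl_proj.frozen = True

    def forward(self, feats):
        if len(feats) != len(self.ch):
            raise ValueError(f"expected {len(self.ch)} scales, got {len(feats)}")
        out = []
        for x, pc, fu, rg, cl, sc in zip(feats, self.pconvs, self.fuses,
                                         self.regs, self.clss, self.scales):
            y = fu(pc(x)).silu()
            out.append((rg(y) * sc, cl(y)))
        return out


def dfl_expectation(dist_logits, reg_max):
    """Distribution-focal decode: per-side offset = sum_j j * softmax(dist)_j.

    ``dist_logits``: (..., 4, reg_max) array or Tensor; returns (..., 4).
    """
    if isinstance(dist_logits, Tensor):
        p = dist_logits.softmax(axis=-1)
        proj = Tensor(_dfl_proj(reg_max).astype(dist_logits.data.dtype))
        return (p * proj).sum(axis=-1)
    z = dist_logits - dist_logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    return (p * np.arange(reg_max)).sum(axis=-1)


def make_anchors(shapes, strides, offset=0.5):
    """Anchor centres (in pixels) and per-anchor stride for 3 scale maps."""
    pts, strs = [], []
    for (h, w), s in zip(shapes, strides):
        xs = (np.arange(w) + offset) * s
        ys = (np.arange(h) + offset) * s
        gx, gy = np.meshgrid(xs, ys)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=-1))
        strs.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(pts), np.concatenate(strs)


def decode_boxes(reg_maps, reg_max, strides=(8, 16, 32)):
    """Decode distribution maps into xyxy pixel boxes for every anchor.

    ``reg_maps``: per-scale arrays (B, 4*reg_max, H, W).  Returns
    (boxes (B, A, 4), anchor centres (A, 2), anchor strides (A,)).
    """
    shapes = [m.shape[2:] for m in reg_maps]
    centers, strs = make_anchors(shapes, strides)
    flat = []
    for m in reg_maps:
        B, C, H, W = m.shape
        flat.append(m.reshape(B, 4, reg_max, H * W).transpose(0, 3, 1, 2))
    dist = np.concatenate(flat, axis=1)            # (B, A, 4, reg_max)
    ltrb = dfl_expectation(dist, reg_max) * strs[None, :, None]
    x1y1 = centers[None] - ltrb[..., :2]
    x2y2 = centers[None] + ltrb[..., 2:]
    return np.concatenate([x1y1, x2y2], axis=-1), centers, strs


def box_iou(a, b):
    """IoU matrix between two xyxy box arrays (N,4) x (M,4)."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        return np.zeros((len(a), len(b)))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(boxes, scores, iou_thr):
    """Greedy class-agnostic NMS; ties broken by lower box index."""
    order = np.lexsort((np.arange(len(scores)), -np.asarray(scores)))
    keep, suppressed = [], np.zeros(len(scores), dtype=bool)
    iou = box_iou(boxes, boxes)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        suppressed |= iou[i] > iou_thr
        suppressed[i] = True
    return keep


def postprocess(head_out, conf_thr=0.25, iou_thr=0.45, reg_max=16, image_id=0):
    """Raw HeadOutput -> sorted Detections (sigmoid scores, DFL decode, NMS)."""
    reg_maps = [np.asarray(r.data if isinstance(r, Tensor) else r) for r, _ in head_out]
    cls_maps = [np.asarray(c.data if isinstance(c, Tensor) else c) for _, c in head_out]
    boxes, _, _ = decode_boxes(reg_maps, reg_max)
    scores = np.concatenate(
        [_sig(m.reshape(m.shape[0], m.shape[1], -1)) for m in cls_maps], axis=2
    ).transpose(0, 2, 1)                            # (B, A, nc)
    dets = []
    B = boxes.shape[0]
    for b in range(B):
        cls_id = scores[b].argmax(axis=1)
        conf = scores[b].max(axis=1)
        m = conf > conf_thr
        bx, cl, cf = boxes[b][m], cls_id[m], conf[m]
        valid = (bx[:, 2] > bx[:, 0]) & (bx[:, 3] > bx[:, 1])
        bx, cl, cf = bx[valid], cl[valid], cf[valid]
        picked = []
        for c in np.unique(cl):
            idx = np.flatnonzero(cl == c)
            for j in nms(bx[idx], cf[idx], iou_thr):
                picked.append(idx[j])
        picked.sort(key=lambda i: (-cf[i], i))
        for i in picked:
            dets.append(Detection(image_id + b, int(cl[i]),
                                  tuple(float(v) for v in bx[i]), float(cf[i])))
    return dets
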