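"""Training loop: SGD with momentum, linear LR decay, optional early stop.

Defaults mirror the study's training recipe (200 epochs, batch 32, SGD,
lr0 0.01, final LR fraction 0.01, weight decay 5e-4, momentum 0.937,
640 px inputs); desk-scale runs override epochs/batch/imgsz.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .nn import Tensor
from .model import build_model, letterbox, save_checkpoint
from .losses import DetectionLoss, LossWeights
from .heads import postprocess
from .yolo_io import read_yolo_label, GroundTruth
from . import metrics as M

__all__ = ["RunConfig", "SGD", "load_items", "train", "evaluate"]


@dataclass
class RunConfig:
    epochs: int = 200
    batch_size: int = 32
    workers: int = 8            # kept for config parity; loading is in-process
    imgsz: int = 640
    optimizer: str = "SGD"
    lr0: float = 0.01
    lrf: float = 0.01
    weight_decay: float = 0.0005
    momentum: float = 0.937
    seed: int = 0
    variant: str = "v8n-DE"
    data: str = ""
    nc: int = 6
    patience: int = 50
    mosaic: bool = False   # 2x2 mosaic augmentation (full-scale runs)
    warmup_epochs: float = 1.0
    box_weight: float = 7.5
    dfl_weight: float = 1.5
    cls_weight: float = 0.5

    def __post_init__(self):
        for name in ("epochs", "batch_size", "imgsz", "lr0", "momentum"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class SGD:
    def __init__(self, params, lr, momentum=0.937, weight_decay=0.0005, clip_norm=10.0):
        self.params = [p for p in params if not getattr(p, "frozen", False)]
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self.clip_norm = clip_norm
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        scale = 1.0
        if self.clip_norm:
            total = sum(float((p.grad ** 2).sum()) for p in self.params if p.grad is not None)
            norm = np.sqrt(total)
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32) * scale
            if self.wd and p.data.ndim > 1:
                g = g + self.wd * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    """Adam with decoupled weight decay; robust to per-layer gradient scale."""

    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = [p for p in params if not getattr(p, "frozen", False)]
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, betas[0], betas[1], eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.wd and p.data.ndim > 1:
                upd = upd + self.wd * p.data
            p.data = p.data - self.lr * upd

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def recalibrate_bn(model, batches, momentum=0.5, passes=2):
    """Refresh BN running statistics under the final weights.

    Small-batch training leaves running estimates lagging the weights they
    normalize for; a few forward passes with a high-momentum update aligns
    eval-mode statistics with the trained model.
    """
    from .nn.modules import BatchNorm2d
    from .nn import no_grad

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [b.momentum for b in bns]
    for b in bns:
        b.momentum = momentum
    model.train()
    with no_grad():
        for _ in range(passes):
            for xb in batches:
                model(Tensor(xb))
    for b, mo in zip(bns, saved):
        b.momentum = mo
    model.eval()
    return model


def load_items(data_yaml, split):
    import yaml as _yaml

    cfg = _yaml.safe_load(Path(data_yaml).read_text())
    if split not in cfg:
        raise FileNotFoundError(f"split {split!r} not in {data_yaml}")
    items = []
    for img in cfg[split]:
        lbl = str(img).replace("images", "labels").rsplit(".", 1)[0] + ".txt"
        items.append({"image": img, "label": lbl})
    return items, cfg.get("nc", 6)


def _load_sample(item, imgsz):
    from PIL import Image

    img = np.asarray(Image.open(item["image"]))
    h, w = img.shape[:2]
    gts = read_yolo_label(item["label"], (w, h))
    lb, meta = letterbox(img, imgsz)
    boxes = meta.boxes_to_letterbox(np.array([g.box for g in gts])) if gts else np.zeros((0, 4))
    labels = np.array([g.class_id for g in gts], dtype=int)
    x = lb.astype(np.float32).transpose(2, 0, 1) / 255.0
    return x, boxes, labels, meta, gts


def _mosaic_sample(cache, rng):
    """2x2 mosaic of four cached samples at their common size."""
    picks = [cache[int(rng.integers(0, len(cache)))] for _ in range(4)]
    C, H, W = picks[0][0].shape
    out = np.zeros((C, H, W), dtype=np.float32)
    qh, qw = H // 2, W // 2
    boxes, labels = [], []
    for q, (x, b, l, *_rest) in enumerate(picks):
        oy, ox = (q // 2) * qh, (q % 2) * qw
        out[:, oy:oy + qh, ox:ox + qw] = x[:, ::2, ::2][:, :qh, :qw]
        if len(b):
            nb = b * 0.5 + np.array([ox, oy, ox, oy])
            keep = (nb[:, 2] - nb[:, 0] >= 2) & (nb[:, 3] - nb[:, 1] >= 2)
            boxes.append(nb[keep])
            labels.append(np.asarray(l)[keep])
    boxes = np.concatenate(boxes) if boxes else np.zeros((0, 4))
    labels = np.concatenate(labels) if labels else np.zeros(0, dtype=int)
    return out, boxes, labels


def train(config: RunConfig, items=None, val_items=None, out_dir=None, log=print):
    """Train a variant on a dataset; returns (model, history)."""
    rng = np.random.default_rng(np.random.PCG64(config.seed))
    if items is None:
        items, nc = load_items(config.data, "train")
        config.nc = nc
        try:
            val_items, _ = load_items(config.data, "val")
        except FileNotFoundError:
            val_items = None
    model = build_model(config.variant, nc=config.nc, seed=config.seed)
    crit = DetectionLoss(config.nc, reg_max=model.reg_max,
                         weights=LossWeights(config.box_weight, config.dfl_weight, config.cls_weight))
    if config.optimizer.lower() == "adam":
        opt = Adam(model.parameters(), config.lr0, weight_decay=config.weight_decay)
    else:
        opt = SGD(model.parameters(), config.lr0, config.momentum, config.weight_decay)
    cache = [_load_sample(it, config.imgsz) for it in items]
    n = len(cache)
    steps_per_epoch = max(1, (n + config.batch_size - 1) // config.batch_size)
    warmup_steps = max(1, int(config.warmup_epochs * steps_per_epoch))
    history = {"epoch_loss": [], "val_map50": [], "config": asdict(config)}
    best_map, best_epoch = -1.0, -1
    step = 0
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        tot, t0 = 0.0, time.time()
        for s in range(steps_per_epoch):
            idx = order[s * config.batch_size:(s + 1) * config.batch_size]
            if idx.size == 0:
                continue
            batch = []
            for i in idx:
                if config.mosaic and rng.random() < 0.5:
                    batch.append(_mosaic_sample(cache, rng))
                else:
                    batch.append((cache[i][0], cache[i][1], cache[i][2]))
            xs = np.stack([b[0] for b in batch])
            targets = [(b[1], b[2]) for b in batch]
            # linear warmup then linear decay to lr0*lrf
            if step < warmup_steps:
                lr = config.lr0 * (step + 1) / warmup_steps
            else:
                frac = epoch / max(1, config.epochs - 1)
                lr = config.lr0 * (1 - frac * (1 - config.lrf))
            opt.lr = lr
            out = model(Tensor(xs))
            loss, parts = crit(out, targets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += parts["total"] * idx.size
            step += 1
        epoch_loss = tot / n
        history["epoch_loss"].append(epoch_loss)
        msg = f"epoch {epoch + 1}/{config.epochs} loss {epoch_loss:.4f} ({time.time() - t0:.1f}s)"
        if val_items:
            res = evaluate(model, val_items, imgsz=config.imgsz, nc=config.nc)
            history["val_map50"].append(res["map50"])
            msg += f" val mAP50 {res['map50']:.1f}"
            if res["map50"] > best_map:
                best_map, best_epoch = res["map50"], epoch
            elif epoch - best_epoch >= config.patience:
                log(msg + "  [early stop]")
                break
        log(msg)
    # align eval-mode BN statistics with the final weights
    calib = [np.stack([cache[i][0] for i in range(s, min(s + config.batch_size, n))])
             for s in range(0, n, config.batch_size)]
    recalibrate_bn(model, calib)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out_dir / "model.npz")
        (out_dir / "history.json").write_text(json.dumps(history, indent=1))
    return model, history


def evaluate(model, items, imgsz=640, nc=6, conf_thr=0.25, iou_thr=0.45, tally_iou=0.45):
    """Run inference over items; returns P/R/mAP + TIDE + tally report."""
    model.eval()
    all_dets, all_gts = [], []
    for i, it in enumerate(items):
        x, boxes, labels, meta, _ = _load_sample(it, imgsz)
        out = model.predict(x[None])
        dets = postprocess(out, conf_thr=conf_thr, iou_thr=iou_thr,
                           reg_max=model.reg_max, image_id=i)
        all_dets += dets
        for b, c in zip(boxes, labels):
            all_gts.append(GroundTruth(i, int(c), tuple(b)))
    m50 = M.mean_average_precision(all_dets, all_gts, nc, (0.5,))
    m5095 = M.mean_average_precision(all_dets, all_gts, nc, tuple(np.arange(0.5, 0.96, 0.05)))
    tp = fp = fn = 0
    by_img = {}
    for g in all_gts:
        by_img.setdefault(g.image_id, ([], []))[1].append(g)
    for d in all_dets:
        by_img.setdefault(d.image_id, ([], []))[0].append(d)
    for dets, gts in by_img.values():
        mr = M.match_detections(sorted(dets, key=lambda d: -d.confidence), gts, 0.5)
        tp += mr.tp
        fp += mr.fp
        fn += mr.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    tide = M.tide_errors(all_dets, all_gts)
    right, missing, error = M.detection_tally(all_dets, all_gts, tally_iou)
    return {"precision": precision, "recall": recall, "map50": m50, "map50_95": m5095,
            "tide": tide, "tally": (right, missing, error),
            "detections": all_dets, "ground_truths": all_gts}
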