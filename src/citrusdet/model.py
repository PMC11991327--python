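"""Model assembly: the four detector variants and image preprocessing.

Layer indexing follows the published 23-entry graph (backbone 0-9, neck
10-21, head 22) so per-layer profiles are unambiguous.  The ``-D`` variant
replaces all eight C2f sites with DR modules, ``-E`` swaps the decoupled
head for the shared-parameter head, and ``-DE`` does both.

The DR stage widths below are the frozen model config: they are the free
hyper-parameters of the architecture (not derivable from the topology) and
were fixed once so that the per-layer and total parameter/FLOP profile of
the assembled variants reproduces the published accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .nn import Tensor, Module, Conv, no_grad, concat, upsample_nearest2
from .blocks import C2f, SPPF, DRModule
from .heads import DecoupledHead, DetectShared

__all__ = ["VARIANTS", "DR_SITES", "build_model", "Model", "LetterboxMeta", "letterbox",
           "save_checkpoint", "load_checkpoint", "variant_config_yaml"]

#: frozen DR stage widths per replacement site: index -> (c3, c4, c5, n)
DR_SITES = {
    2: (26, 8, 6, 1),
    4: (12, 14, 14, 3),
    6: (64, 32, 32, 1),
    8: (66, 70, 70, 1),
    12: (64, 32, 32, 1),
    15: (32, 16, 16, 1),
    18: (64, 32, 32, 1),
    21: (150, 40, 80, 2),
}

#: baseline graph: (from, block, args);  C2f args = (c1, c2, n, shortcut)
BASE_LAYERS = [
    (-1, "Conv", (3, 16, 3, 2)),        # 0  P1/2
    (-1, "Conv", (16, 32, 3, 2)),       # 1  P2/4
    (-1, "C2f", (32, 32, 1, True)),     # 2
    (-1, "Conv", (32, 64, 3, 2)),       # 3  P3/8
    (-1, "C2f", (64, 64, 2, True)),     # 4
    (-1, "Conv", (64, 128, 3, 2)),      # 5  P4/16
    (-1, "C2f", (128, 128, 2, True)),   # 6
    (-1, "Conv", (128, 256, 3, 2)),     # 7  P5/32
    (-1, "C2f", (256, 256, 1, True)),   # 8
    (-1, "SPPF", (256, 256)),           # 9
    (-1, "Upsample", ()),               # 10
    ([-1, 6], "Concat", ()),            # 11
    (-1, "C2f", (384, 128, 1, False)),  # 12
    (-1, "Upsample", ()),               # 13
    ([-1, 4], "Concat", ()),            # 14
    (-1, "C2f", (192, 64, 1, False)),   # 15 P3 out
    (-1, "Conv", (64, 64, 3, 2)),       # 16
    ([-1, 12], "Concat", ()),           # 17
    (-1, "C2f", (192, 128, 1, False)),  # 18 P4 out
    (-1, "Conv", (128, 128, 3, 2)),     # 19
    ([-1, 9], "Concat", ()),            # 20
    (-1, "C2f", (384, 256, 1, False)),  # 21 P5 out
    ([15, 18, 21], "Detect", ()),       # 22
]

VARIANTS = ("v8n", "v8n-D", "v8n-E", "v8n-DE")
HEAD_CH = (64, 128, 256)


class _Upsample(Module):
    def forward(self, x):
        return upsample_nearest2(x)


class _Concat(Module):
    def forward(self, xs):
        return concat(xs, axis=1)


class Model(Module):
    """Ordered layer graph with backward-only routing references."""

    def __init__(self, variant, nc=6, seed=0):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        if nc < 1:
            raise ValueError("nc must be >= 1")
        self.variant, self.nc = variant, nc
        rng = np.random.default_rng(seed)
        use_dr = variant in ("v8n-D", "v8n-DE")
        use_shared = variant in ("v8n-E", "v8n-DE")
        self.froms = []
        self.layers = []
        for i, (frm, block, args) in enumerate(BASE_LAYERS):
            if block == "C2f" and use_dr:
                c1, c2, _, _ = args
                c3, c4, c5, n = DR_SITES[i]
                m = DRModule(c1, c2, c3, c4, c5, n, rng=rng)
            elif block == "C2f":
                m = C2f(*args, rng=rng)
            elif block == "Conv":
                c1, c2, k, s = args
                m = Conv(c1, c2, k, s, rng=rng)
            elif block == "SPPF":
                m = SPPF(*args, rng=rng)
            elif block == "Upsample":
                m = _Upsample()
            elif block == "Concat":
                m = _Concat()
            elif block == "Detect":
                head_cls = DetectShared if use_shared else DecoupledHead
                m = head_cls(nc=nc, ch=HEAD_CH, rng=rng)
            else:  # pragma: no cover
                raise AssertionError(block)
            self.froms.append(frm)
            self.layers.append(m)
        self.strides = (8, 16, 32)
        self.reg_max = self.layers[-1].reg_max

    @property
    def head(self):
        return self.layers[-1]

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        B, C, H, W = x.shape
        if H % 32 or W % 32:
            raise ValueError(f"input spatial dims must be multiples of 32, got {H}x{W}")
        outputs = []
        y = x
        for i, (frm, m) in enumerate(zip(self.froms, self.layers)):
            if isinstance(frm, list):
                inp = [y if j == -1 else outputs[j] for j in frm]
                y = m(inp)
            else:
                y = m(y if frm == -1 else outputs[frm])
            outputs.append(y)
        return y  # HeadOutput: [(reg, cls) x 3 scales]

    def predict(self, x):
        self.eval()
        with no_grad():
            return self.forward(x)

    def merge_reparam(self):
        """Collapse every dilated-reparam block for deployment."""
        for m in self.layers:
            if isinstance(m, DRModule):
                m.merge_reparam()
        return self


def build_model(variant: str, nc: int = 6, seed: int = 0) -> Model:
    return Model(variant, nc=nc, seed=seed)


def variant_config_yaml(variant: str, nc: int = 6) -> str:
    """Serializable per-layer config mirroring the 0-22 indexing."""
    use_dr = variant in ("v8n-D", "v8n-DE")
    rows = []
    for i, (frm, block, args) in enumerate(BASE_LAYERS):
        if block == "C2f" and use_dr:
            block, args = "DR", tuple(args[:2]) + DR_SITES[i]
        if block == "Detect" and variant in ("v8n-E", "v8n-DE"):
            block = "DetectShared"
        rows.append({"index": i, "from": frm, "block": block, "args": list(args)})
    return yaml.safe_dump({"variant": variant, "nc": nc, "layers": rows}, sort_keys=False)


# ------------------------------------------------------------------ letterbox
@dataclass
class LetterboxMeta:
    ratio: float
    pad_left: int
    pad_top: int
    orig_size: tuple  # (h, w)

    def boxes_to_letterbox(self, boxes):
        b = np.asarray(boxes, dtype=np.float64).copy()
        b[..., [0, 2]] = b[..., [0, 2]] * self.ratio + self.pad_left
        b[..., [1, 3]] = b[..., [1, 3]] * self.ratio + self.pad_top
        return b

    def boxes_to_original(self, boxes):
        b = np.asarray(boxes, dtype=np.float64).copy()
        b[..., [0, 2]] = (b[..., [0, 2]] - self.pad_left) / self.ratio
        b[..., [1, 3]] = (b[..., [1, 3]] - self.pad_top) / self.ratio
        return b


def letterbox(image: np.ndarray, target: int = 640, pad_value: int = 114):
    """Aspect-preserving resize + centered gray padding to target x target."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[:, :, None].repeat(3, axis=2)
    h, w = img.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    ratio = min(target / h, target / w)
    nh, nw = max(1, round(h * ratio)), max(1, round(w * ratio))
    if (nh, nw) != (h, w):
        from PIL import Image

        img = np.asarray(Image.fromarray(img.astype(np.uint8)).resize((nw, nh), Image.BILINEAR))
    top = (target - nh) // 2
    left = (target - nw) // 2
    out = np.full((target, target, img.shape[2]), pad_value, dtype=img.dtype)
    out[top:top + nh, left:left + nw] = img
    return out, LetterboxMeta(ratio, left, top, (h, w))


# ----------------------------------------------------------------- checkpoint
def save_checkpoint(model: Model, path):
    arrays = {name: p.data for name, p in model.named_parameters()}
    arrays["__meta_variant"] = np.array(model.variant)
    arrays["__meta_nc"] = np.array(model.nc)
    # BN running stats
    for i, m in enumerate(model.modules()):
        if hasattr(m, "running_mean"):
            arrays[f"__bn{i}.mean"] = m.running_mean
            arrays[f"__bn{i}.var"] = m.running_var
    np.savez_compressed(path, **arrays)


def load_checkpoint(path, seed: int = 0) -> Model:
    data = np.load(path, allow_pickle=False)
    variant = str(data["__meta_variant"])
    nc = int(data["__meta_nc"])
    model = build_model(variant, nc=nc, seed=seed)
    for name, p in model.named_parameters():
        if name not in data:
            raise KeyError(f"checkpoint missing parameter {name}")
        arr = data[name]
        if arr.shape != p.data.shape:
            raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
        p.data = arr.astype(np.float32)
    for i, m in enumerate(model.modules()):
        if hasattr(m, "running_mean") and f"__bn{i}.mean" in data:
            m.running_mean = data[f"__bn{i}.mean"]
            m.running_var = data[f"__bn{i}.var"]
    return model
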