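"""Seeded synthetic citrus-leaf scenes with six lesion morphologies.

Stands in for field-collected orchard imagery: every stage of the pipeline
(annotation I/O, training, evaluation, error analysis) runs against these
scenes without any download.  Six programmatically distinct classes follow
the field's labelling scheme:

=====  =====================  ==========================================
class  label                  morphology rendered
=====  =====================  ==========================================
0      a  anthracnose         cluster of dark punctate spots
1      c  canker              raised circular lesion with concentric ring
2      h  Huanglongbing       asymmetric yellow mottling
3      m  melanose            dense black micro-dots
4      n  nutrition def.      diffuse low-contrast chlorosis (hardest)
5      p  pest perforation    hole with a dark rim
=====  =====================  ==========================================

Class ``n`` is deliberately rendered at low contrast — it is the hardest
category in the field data.  Default class frequencies mimic the study's
imbalanced distribution (canker is the 160-image minority class).
Everything is deterministic under a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .yolo_io import GroundTruth, write_yolo_label, read_yolo_label

__all__ = ["CLASS_NAMES", "CLASS_FREQS", "LesionSpec", "SceneSpec", "DatasetManifest",
           "render_scene", "random_scene_spec", "generate_dataset", "split_dataset",
           "oversample_class"]

CLASS_NAMES = ("a", "c", "h", "m", "n", "p")
#: image counts per class in the study's distribution (used as sampling weights)
CLASS_FREQS = (1263, 160, 1416, 1770, 708, 733)

#: easy-mode lesion colors, chosen to be linearly separable in RGB
EASY_PALETTE = {
    0: (160, 30, 20),     # a: red-brown
    1: (235, 225, 205),   # c: near-white
    2: (235, 220, 35),    # h: bright yellow
    3: (10, 10, 10),      # m: black
    4: (60, 170, 200),    # n: teal
    5: (150, 30, 160),    # p: magenta
}


@dataclass
class LesionSpec:
    class_id: int
    center: tuple       # (x, y) pixels
    size: float         # characteristic radius, pixels
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.class_id < len(CLASS_NAMES):
            raise ValueError(f"class_id {self.class_id} out of range")
        if self.size <= 0:
            raise ValueError("lesion size must be positive")


@dataclass
class SceneSpec:
    size: tuple = (256, 256)    # (h, w)
    background_seed: int = 0
    lesions: list = field(default_factory=list)
    easy: bool = False          # plain background, high contrast


@dataclass
class DatasetManifest:
    root: str
    class_names: tuple = CLASS_NAMES
    splits: dict = field(default_factory=dict)   # split -> list of items
    # item: {"image": path, "label": path, "class": primary class id, "origin": str}

    def counts(self):
        return {s: len(v) for s, v in self.splits.items()}

    def all_items(self):
        return [it for v in self.splits.values() for it in v]

    def to_yaml(self, path):
        data = {
            "path": str(self.root),
            "names": {i: n for i, n in enumerate(self.class_names)},
            "nc": len(self.class_names),
        }
        for split, items in self.splits.items():
            data[split] = [str(it["image"]) for it in items]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# --------------------------------------------------------------- rendering
def _smooth_noise(rng, h, w, scale=8, amp=1.0):
    coarse = rng.standard_normal((h // scale + 2, w // scale + 2))
    up = np.kron(coarse, np.ones((scale, scale)))[:h, :w]
    return up * amp


def _background(rng, h, w, easy):
    if easy:
        base = np.array([60.0, 120.0, 45.0])
        img = np.ones((h, w, 3)) * base
        img += rng.standard_normal((h, w, 3)) * 2.0
        return img
    base = np.array([50.0, 110.0, 40.0]) + rng.uniform(-12, 12, 3)
    img = np.ones((h, w, 3)) * base
    grad = np.linspace(-14, 14, h)[:, None]
    img[..., 1] += grad
    img[..., 1] += _smooth_noise(rng, h, w, 16, 7.0)
    img[..., 0] += _smooth_noise(rng, h, w, 8, 5.0)
    img += rng.standard_normal((h, w, 3)) * 3.0
    # faint veins
    for _ in range(3):
        y0 = rng.integers(0, h)
        thickness = rng.integers(1, 3)
        img[max(0, y0):y0 + thickness, :, 1] += 10
    return img


def _patch_grid(cx, cy, r, h, w):
    x0, x1 = int(max(0, cx - r)), int(min(w, cx + r + 1))
    y0, y1 = int(max(0, cy - r)), int(min(h, cy + r + 1))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    return x0, x1, y0, y1, xs, ys


def _paint(img, mask, color, strength=1.0):
    for c in range(3):
        img[..., c] += mask * (color[c] - img[..., c]) * strength


def _draw_lesion(img, les: LesionSpec, rng, easy):
    h, w = img.shape[:2]
    cx, cy = les.center
    r = les.size
    margin = r * 1.6
    if not (margin <= cx <= w - margin and margin <= cy <= h - margin):
        raise ValueError(f"lesion at {les.center} size {r} out of bounds for {w}x{h}")
    x0, x1, y0, y1, xs, ys = _patch_grid(cx, cy, int(margin), h, w)
    patch = img[y0:y1, x0:x1]
    d = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)
    k = les.class_id
    contrast = 1.0 if easy else 0.85
    drawn = np.zeros(d.shape, dtype=bool)
    # easy mode: maximally separable class palette (diagnostic fixture, not realism)
    palette = EASY_PALETTE[k] if easy else None

    if k == 0:      # anthracnose: punctate dark spots
        color = palette or (70, 40, 25)
        n_spots = les.params.get("spot_count", int(rng.integers(3, 9)))
        for _ in range(n_spots):
            ang, rad = rng.uniform(0, 2 * np.pi), rng.uniform(0, r)
            sx, sy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            sr = rng.uniform(r * 0.12, r * 0.25) + 1.5
            m = np.clip(1.0 - np.sqrt((xs - sx) ** 2 + (ys - sy) ** 2) / sr, 0, 1)
            _paint(patch, m, color, contrast)
            drawn |= m > 0.1
    elif k == 1:    # canker: ringed raised lesion
        core_c = palette or (150, 120, 70)
        ring_c = (90, 55, 30) if palette is None else tuple(v * 0.5 for v in palette)
        ring = np.exp(-((d - r * 0.75) / (r * 0.16)) ** 2)
        core = np.clip(1.0 - d / (r * 0.55), 0, 1)
        _paint(patch, core, core_c, contrast)
        _paint(patch, ring, ring_c, contrast)
        halo = np.exp(-((d - r) / (r * 0.2)) ** 2)
        _paint(patch, halo, (140, 150, 60), 0.5 * contrast)
        drawn |= (core > 0.1) | (ring > 0.15) | (halo > 0.2)
    elif k == 2:    # HLB: asymmetric yellow mottling
        color = palette or (190, 185, 60)
        blotch = _smooth_noise(rng, *d.shape, max(2, int(r / 3)), 1.0)
        stretch = ((xs - cx) / (1.4 * r)) ** 2 + ((ys - cy) / (0.8 * r)) ** 2
        m = np.clip(1.0 - stretch, 0, 1) * np.clip(blotch + 0.7, 0, 1.2)
        m = np.clip(m, 0, 1)
        _paint(patch, m, color, contrast)
        drawn |= m > 0.12
    elif k == 3:    # melanose: dense micro-dots
        color = palette or (35, 25, 20)
        n_dots = les.params.get("dot_count", int(rng.integers(25, 60)))
        for _ in range(n_dots):
            ang, rad = rng.uniform(0, 2 * np.pi), r * np.sqrt(rng.uniform(0, 1))
            sx, sy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            sr = rng.uniform(1.0, 2.5)
            m = np.clip(1.0 - np.sqrt((xs - sx) ** 2 + (ys - sy) ** 2) / sr, 0, 1)
            _paint(patch, m, color, contrast)
            drawn |= m > 0.1
    elif k == 4:    # nutrition deficiency: diffuse low-contrast chlorosis
        color = palette or (150, 160, 70)
        m = np.clip(1.0 - d / (1.4 * r), 0, 1) ** 1.5
        strength = 0.9 if easy else 0.35   # deliberately faint in realistic mode
        _paint(patch, m, color, strength)
        drawn |= m > (0.1 if easy else 0.25)
    else:           # pest perforation: hole with dark rim
        hole_c = palette or (25, 18, 12)
        rim_c = (80, 50, 30) if palette is None else tuple(min(255, v * 1.6) for v in palette)
        rim = np.exp(-((d - r * 0.7) / (r * 0.15)) ** 2)
        hole = np.clip(1.0 - d / (r * 0.6), 0, 1)
        _paint(patch, hole, hole_c, contrast)
        _paint(patch, rim, rim_c, contrast)
        drawn |= (hole > 0.1) | (rim > 0.2)

    ys_d, xs_d = np.nonzero(drawn)
    if ys_d.size == 0:
        raise ValueError("lesion rendered no pixels")
    x1b, x2b = x0 + xs_d.min(), x0 + xs_d.max() + 1
    y1b, y2b = y0 + ys_d.min(), y0 + ys_d.max() + 1
    return (float(x1b), float(y1b), float(x2b), float(y2b))


def render_scene(spec: SceneSpec, seed: int = 0):
    """Deterministic scene draw -> (uint8 image HxWx3, GroundTruth list)."""
    h, w = spec.size
    rng = np.random.default_rng(np.random.PCG64(seed * 1_000_003 + spec.background_seed))
    img = _background(rng, h, w, spec.easy)
    gts = []
    for les in spec.lesions:
        box = _draw_lesion(img, les, rng, spec.easy)
        gts.append(GroundTruth(0, les.class_id, box))
    return np.clip(img, 0, 255).astype(np.uint8), gts


def random_scene_spec(rng, size=(256, 256), n_lesions=(1, 4), classes=None,
                      class_probs=None, easy=False):
    h, w = size
    if classes is None:
        classes = tuple(range(len(CLASS_NAMES)))
    if class_probs is None:
        if easy:
            # the easy fixture probes learnability, not imbalance: uniform classes
            class_probs = np.full(len(classes), 1.0 / len(classes))
        else:
            freqs = np.array([CLASS_FREQS[c] for c in classes], dtype=float)
            class_probs = freqs / freqs.sum()
    n = int(rng.integers(n_lesions[0], n_lesions[1] + 1))
    lesions = []
    for _ in range(n):
        k = int(rng.choice(classes, p=class_probs))
        if easy:
            r = rng.uniform(0.14, 0.2) * min(h, w)
        else:
            r = rng.uniform(0.05, 0.12) * min(h, w)
        margin = r * 1.7 + 2
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        lesions.append(LesionSpec(k, (cx, cy), r))
    return SceneSpec((h, w), int(rng.integers(0, 2 ** 31 - 1)), lesions, easy)


# ----------------------------------------------------------------- datasets
def generate_dataset(root, n_images, seed=0, size=(256, 256), n_lesions=(1, 4),
                     easy=False, class_probs=None, split_ratios=(8, 1, 1)):
    """Render ``n_images`` scenes, write PNGs + YOLO labels, split, dump YAML."""
    from PIL import Image

    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "labels").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(np.random.PCG64(seed))
    items = []
    for i in range(n_images):
        spec = random_scene_spec(master, size=size, n_lesions=n_lesions,
                                 class_probs=class_probs, easy=easy)
        img, gts = render_scene(spec, seed=int(master.integers(0, 2 ** 31 - 1)))
        img_path = root / "images" / f"{i:05d}.png"
        lbl_path = root / "labels" / f"{i:05d}.txt"
        Image.fromarray(img).save(img_path)
        write_yolo_label(gts, (size[1], size[0]), lbl_path)
        primary = gts[0].class_id if gts else 0
        items.append({"image": str(img_path), "label": str(lbl_path),
                      "class": primary, "origin": "render"})
    manifest = split_dataset(items, ratios=split_ratios, seed=seed, root=str(root))
    manifest.to_yaml(root / "data.yaml")
    return manifest


def split_dataset(items, ratios=(8, 1, 1), seed=0, root="."):
    """Per-class stratified shuffle split.

    Per class: train = floor(n * r_train / sum), the remainder alternates
    val first, then test (n=10 at 8:1:1 gives 8/1/1).
    """
    if min(ratios) < 0 or sum(ratios) <= 0:
        raise ValueError("ratios must be positive")
    if isinstance(items, DatasetManifest):
        items = items.all_items()
    rng = np.random.default_rng(np.random.PCG64(seed))
    by_class = {}
    for it in items:
        by_class.setdefault(it["class"], []).append(it)
    splits = {"train": [], "val": [], "test": []}
    total = sum(ratios)
    for c in sorted(by_class):
        group = list(by_class[c])
        rng.shuffle(group)
        n = len(group)
        n_train = n * ratios[0] // total
        rem = n - n_train
        n_val = (rem + 1) // 2 if ratios[1] else 0
        splits["train"] += group[:n_train]
        splits["val"] += group[n_train:n_train + n_val]
        splits["test"] += group[n_train + n_val:]
    return DatasetManifest(root=str(root), splits=splits)


# ------------------------------------------------------------- augmentation
def _hsv_jitter(img, rng, mag=0.15):
    scale = 1.0 + rng.uniform(-mag, mag, 3)
    return np.clip(img.astype(np.float64) * scale, 0, 255).astype(np.uint8)


def _flip_lr(img, gts):
    w = img.shape[1]
    out = []
    for g in gts:
        x1, y1, x2, y2 = g.box
        out.append(GroundTruth(g.image_id, g.class_id, (w - x2, y1, w - x1, y2)))
    return img[:, ::-1].copy(), out


def _mosaic4(imgs, gts_lists):
    """2x2 mosaic of four equal-size images; boxes shifted accordingly."""
    h, w = imgs[0].shape[:2]
    canvas = np.zeros((2 * h, 2 * w, 3), dtype=imgs[0].dtype)
    offsets = [(0, 0), (0, w), (h, 0), (h, w)]
    gts = []
    for img, gl, (oy, ox) in zip(imgs, gts_lists, offsets):
        canvas[oy:oy + h, ox:ox + w] = img
        for g in gl:
            x1, y1, x2, y2 = g.box
            gts.append(GroundTruth(g.image_id, g.class_id, (x1 + ox, y1 + oy, x2 + ox, y2 + oy)))
    # scale back to original size
    from PIL import Image

    small = np.asarray(Image.fromarray(canvas).resize((w, h), Image.BILINEAR))
    gts = [GroundTruth(g.image_id, g.class_id,
                       tuple(v / 2 for v in g.box)) for g in gts]
    gts = [g for g in gts if g.box[2] - g.box[0] >= 2 and g.box[3] - g.box[1] >= 2]
    return small, gts


def oversample_class(manifest: DatasetManifest, class_id, target_count, seed=0,
                     split="train"):
    """Expand a minority class to ``target_count`` items via augmented copies
    (flip, HSV jitter, mosaic).  Returns a new manifest; originals untouched.
    """
    import warnings
    from PIL import Image

    rng = np.random.default_rng(np.random.PCG64(seed))
    items = manifest.splits[split]
    pool = [it for it in items if it["class"] == class_id]
    if not pool:
        raise ValueError(f"class {class_id} not present in split {split!r}")
    if target_count <= len(pool):
        if target_count < len(pool):
            warnings.warn("target below current count; no-op")
        return manifest
    root = Path(manifest.root)
    aug_img_dir = root / "images_aug"
    aug_lbl_dir = root / "labels_aug"
    aug_img_dir.mkdir(exist_ok=True)
    aug_lbl_dir.mkdir(exist_ok=True)
    new_items = list(items)
    i = 0
    while len([it for it in new_items if it["class"] == class_id]) < target_count:
        mode = ("flip", "hsv", "mosaic")[int(rng.integers(0, 3))]
        src = pool[int(rng.integers(0, len(pool)))]
        img = np.asarray(Image.open(src["image"]))
        h, w = img.shape[:2]
        gts = read_yolo_label(src["label"], (w, h))
        if mode == "flip":
            img, gts = _flip_lr(img, gts)
        elif mode == "hsv":
            img = _hsv_jitter(img, rng)
        else:
            picks = [pool[int(rng.integers(0, len(pool)))] for _ in range(3)]
            imgs = [img] + [np.asarray(Image.open(p["image"])) for p in picks]
            gls = [gts] + [read_yolo_label(p["label"], (w, h)) for p in picks]
            img, gts = _mosaic4(imgs, gls)
        img_path = aug_img_dir / f"aug_{class_id}_{i:05d}.png"
        lbl_path = aug_lbl_dir / f"aug_{class_id}_{i:05d}.txt"
        Image.fromarray(img).save(img_path)
        write_yolo_label(gts, (w, h), lbl_path)
        new_items.append({"image": str(img_path), "label": str(lbl_path),
                          "class": class_id, "origin": f"aug:{mode}:{Path(src['image']).name}"})
        i += 1
    splits = dict(manifest.splits)
    splits[split] = new_items
    return DatasetManifest(root=manifest.root, class_names=manifest.class_names, splits=splits)
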