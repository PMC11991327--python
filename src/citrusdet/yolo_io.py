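"""YOLO-format annotation and prediction text I/O.

Labels: one ``class cx cy w h`` line per object, coordinates normalized to
[0, 1].  Predictions add a confidence column: ``class conf cx cy w h``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .heads import Detection

__all__ = ["GroundTruth", "write_yolo_label", "read_yolo_label",
           "write_predictions", "read_predictions", "xywhn_to_xyxy", "xyxy_to_xywhn"]


@dataclass
class GroundTruth:
    image_id: int
    class_id: int
    box: tuple  # (x1, y1, x2, y2) pixels

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}")


def xywhn_to_xyxy(cx, cy, w, h, img_w, img_h):
    return ((cx - w / 2) * img_w, (cy - h / 2) * img_h,
            (cx + w / 2) * img_w, (cy + h / 2) * img_h)


def xyxy_to_xywhn(box, img_w, img_h):
    x1, y1, x2, y2 = box
    return ((x1 + x2) / 2 / img_w, (y1 + y2) / 2 / img_h,
            (x2 - x1) / img_w, (y2 - y1) / img_h)


def write_yolo_label(gts, image_size, path):
    """``gts``: GroundTruth list (pixel boxes); image_size = (w, h)."""
    img_w, img_h = image_size
    lines = []
    for g in gts:
        cx, cy, w, h = xyxy_to_xywhn(g.box, img_w, img_h)
        lines.append(f"{g.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_label(path, image_size, image_id=0):
    """Parse a label file back to pixel-space GroundTruths."""
    img_w, img_h = image_size
    gts = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        cls = int(parts[0])
        cx, cy, w, h = map(float, parts[1:])
        for name, v in zip(("cx", "cy", "w", "h"), (cx, cy, w, h)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}:{ln}: {name}={v} outside [0,1]")
        gts.append(GroundTruth(image_id, cls, xywhn_to_xyxy(cx, cy, w, h, img_w, img_h)))
    return gts


def write_predictions(dets, image_size, path):
    img_w, img_h = image_size
    lines = []
    for d in dets:
        cx, cy, w, h = xyxy_to_xywhn(d.box, img_w, img_h)
        lines.append(f"{d.class_id} {d.confidence:.6f} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_detections_json(dets, path):
    """Machine-readable dump: one object per detection, pixel xyxy boxes."""
    import json

    rows = [{"image_id": d.image_id, "class_id": d.class_id,
             "box": [round(float(v), 3) for v in d.box],
             "confidence": round(float(d.confidence), 5)} for d in dets]
    Path(path).write_text(json.dumps(rows, indent=1))


def read_predictions(path, image_size, image_id=0):
    img_w, img_h = image_size
    dets = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"{path}:{ln}: expected 6 fields, got {len(parts)}")
        cls = int(parts[0])
        conf = float(parts[1])
        cx, cy, w, h = map(float, parts[2:])
        dets.append(Detection(image_id, cls, xywhn_to_xyxy(cx, cy, w, h, img_w, img_h), conf))
    return dets
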