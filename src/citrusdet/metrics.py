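"""Evaluation: greedy matching, precision/recall, AP/mAP, the TIDE error
taxonomy, and the right/missing/error tally.

Matching is confidence-greedy: detections are visited in descending
confidence and claim the highest-IoU unmatched ground truth of the same
class with IoU >= threshold.  AP integrates the precision-recall curve at
101 recall points; mAP averages over classes (classes without ground
truth are excluded) and is reported as a percentage.

TIDE bands classify every false positive by its best overlap: Cls (wrong
class, IoU >= 0.5), Dupe (right class but the ground truth was already
claimed, IoU >= 0.5), Loc (right class, 0.1 <= IoU < 0.5... boundary 0.5
goes to the >=0.5 bands), Both (wrong class, 0.1 <= IoU < 0.5), Bkg
(IoU < 0.1).  Miss counts ground truths no detection overlaps at >= 0.1.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .heads import box_iou

__all__ = ["MatchResult", "TideReport", "match_detections", "precision_recall",
           "average_precision", "mean_average_precision", "map50", "map50_95",
           "tide_errors", "detection_tally"]


@dataclass
class MatchResult:
    det_flags: list            # "TP" | "FP" per detection (input order)
    det_gt: list               # matched gt index or -1
    det_iou: list              # IoU with the matched/best gt
    gt_matched: list           # bool per gt

    @property
    def tp(self):
        return sum(f == "TP" for f in self.det_flags)

    @property
    def fp(self):
        return sum(f == "FP" for f in self.det_flags)

    @property
    def fn(self):
        return sum(not m for m in self.gt_matched)


@dataclass
class TideReport:
    cls: int = 0
    loc: int = 0
    both: int = 0
    dupe: int = 0
    bkg: int = 0
    miss: int = 0
    fp: int = 0
    fn: int = 0
    n_images: int = 1

    def per_100_images(self):
        s = 100.0 / max(self.n_images, 1)
        return {k: round(getattr(self, k) * s, 2)
                for k in ("cls", "loc", "both", "dupe", "bkg", "miss", "fp", "fn")}


def _group(items):
    by_img = defaultdict(list)
    for it in items:
        by_img[it.image_id].append(it)
    return by_img


def match_detections(dets, gts, iou_thr=0.5):
    """Greedy same-class matching for one image's detections and gts."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    det_flags = ["FP"] * len(dets)
    det_gt = [-1] * len(dets)
    det_iou = [0.0] * len(dets)
    gt_matched = [False] * len(gts)
    if gts:
        gboxes = np.array([g.box for g in gts], dtype=np.float64)
        dboxes = np.array([d.box for d in dets], dtype=np.float64) if dets else np.zeros((0, 4))
        iou = box_iou(dboxes, gboxes)
        for i in order:
            best, best_iou = -1, -1.0
            for j, g in enumerate(gts):
                if gt_matched[j] or g.class_id != dets[i].class_id:
                    continue
                if iou[i, j] >= iou_thr and iou[i, j] > best_iou:
                    best, best_iou = j, iou[i, j]
            if best >= 0:
                det_flags[i] = "TP"
                det_gt[i] = best
                det_iou[i] = best_iou
                gt_matched[best] = True
    return MatchResult(det_flags, det_gt, det_iou, gt_matched)


def precision_recall(match: MatchResult):
    """P = TP/(TP+FP), R = TP/(TP+FN); zero denominators give 0."""
    tp, fp, fn = match.tp, match.fp, match.fn
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def average_precision(dets, gts, class_id, iou_thr=0.5, n_points=101):
    """AP for one class over a whole image set (101-point interpolation)."""
    cgts = [g for g in gts if g.class_id == class_id]
    cdets = sorted((d for d in dets if d.class_id == class_id),
                   key=lambda d: (-d.confidence, d.image_id))
    n_gt = len(cgts)
    if n_gt == 0:
        return np.nan
    gts_by_img = _group(cgts)
    matched = {img: [False] * len(v) for img, v in gts_by_img.items()}
    tps = np.zeros(len(cdets))
    for k, d in enumerate(cdets):
        cand = gts_by_img.get(d.image_id, [])
        if not cand:
            continue
        iou = box_iou(np.array([d.box]), np.array([g.box for g in cand]))[0]
        free = [j for j in range(len(cand)) if not matched[d.image_id][j]]
        if not free:
            continue
        j = max(free, key=lambda j: iou[j])
        if iou[j] >= iou_thr:
            tps[k] = 1
            matched[d.image_id][j] = True
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(1 - tps)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    ap = 0.0
    for r in np.linspace(0, 1, n_points):
        mask = recall >= r - 1e-12
        ap += precision[mask].max() if mask.any() else 0.0
    return ap / n_points


def mean_average_precision(dets, gts, n_classes, iou_thrs=(0.5,), n_points=101):
    """mAP (%) averaged over classes with ground truth, then over IoU thresholds."""
    vals = []
    for thr in iou_thrs:
        aps = [average_precision(dets, gts, c, thr, n_points) for c in range(n_classes)]
        aps = [a for a in aps if not np.isnan(a)]
        vals.append(np.mean(aps) if aps else 0.0)
    return float(np.mean(vals) * 100.0)


def map50(dets, gts, n_classes=6):
    return mean_average_precision(dets, gts, n_classes, (0.5,))


def map50_95(dets, gts, n_classes=6):
    return mean_average_precision(dets, gts, n_classes, tuple(np.arange(0.5, 0.96, 0.05)))


def tide_errors(dets, gts, fg_thr=0.5, bg_thr=0.1, match_thr=0.5):
    """Classify every false positive into one TIDE band; count misses."""
    report = TideReport(n_images=max(len({g.image_id for g in gts} | {d.image_id for d in dets}), 1))
    dets_by_img, gts_by_img = _group(dets), _group(gts)
    for img in sorted(set(dets_by_img) | set(gts_by_img)):
        idets = sorted(dets_by_img.get(img, []), key=lambda d: (-d.confidence, d.image_id))
        igts = gts_by_img.get(img, [])
        m = match_detections(idets, igts, match_thr)
        report.fp += m.fp
        report.fn += m.fn
        if igts:
            gboxes = np.array([g.box for g in igts])
            gcls = np.array([g.class_id for g in igts])
        explained = [False] * len(igts)
        for i, d in enumerate(idets):
            if m.det_flags[i] == "TP":
                continue
            if not igts:
                report.bkg += 1
                continue
            iou = box_iou(np.array([d.box]), gboxes)[0]
            same = iou[gcls == d.class_id]
            other = iou[gcls != d.class_id]
            iou_same = same.max() if same.size else 0.0
            iou_other = other.max() if other.size else 0.0
            if iou_other >= fg_thr:
                report.cls += 1
                j = int(np.flatnonzero(gcls != d.class_id)[other.argmax()])
                explained[j] = True
            elif iou_same >= fg_thr:
                report.dupe += 1
            elif iou_same >= bg_thr:
                report.loc += 1
                j = int(np.flatnonzero(gcls == d.class_id)[same.argmax()])
                explained[j] = True
            elif iou_other >= bg_thr:
                report.both += 1
                j = int(np.flatnonzero(gcls != d.class_id)[other.argmax()])
                explained[j] = True
            else:
                report.bkg += 1
        for j, g in enumerate(igts):
            if m.gt_matched[j] or explained[j]:
                continue
            if idets:
                iou = box_iou(np.array([d.box for d in idets]), gboxes[j:j + 1])[:, 0]
                if iou.max() >= bg_thr:
                    continue  # lost to an errored detection, not a pure miss
            report.miss += 1
    return report


def report_csv(dets, gts, n_classes, class_names=None, iou_thr=0.5):
    """Per-class AP table plus the TIDE row, as CSV text."""
    names = class_names or [str(c) for c in range(n_classes)]
    lines = ["class,ap50,n_gt,n_det"]
    for c in range(n_classes):
        ap = average_precision(dets, gts, c, iou_thr)
        ap_s = "" if np.isnan(ap) else f"{ap * 100:.2f}"
        lines.append(f"{names[c]},{ap_s},{sum(g.class_id == c for g in gts)},"
                     f"{sum(d.class_id == c for d in dets)}")
    r = tide_errors(dets, gts)
    lines.append("tide,cls,loc,both,dupe,bkg,miss,fp,fn")
    lines.append(f"counts,{r.cls},{r.loc},{r.both},{r.dupe},{r.bkg},{r.miss},{r.fp},{r.fn}")
    p100 = r.per_100_images()
    lines.append("per_100_images," + ",".join(str(p100[k]) for k in
                                              ("cls", "loc", "both", "dupe", "bkg", "miss", "fp", "fn")))
    return "\n".join(lines)


def detection_tally(dets, gts, iou_thr=0.45):
    """(right, missing, error) over a test set at the stated IoU threshold."""
    right = missing = error = 0
    dets_by_img, gts_by_img = _group(dets), _group(gts)
    for img in sorted(set(dets_by_img) | set(gts_by_img)):
        idets = sorted(dets_by_img.get(img, []), key=lambda d: (-d.confidence, d.image_id))
        m = match_detections(idets, gts_by_img.get(img, []), iou_thr)
        right += m.tp
        error += m.fp
        missing += m.fn
    return right, missing, error
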