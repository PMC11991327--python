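"""Matching, precision/recall, AP, TIDE taxonomy, detection tally."""

import numpy as np
import pytest

from citrusdet.heads import Detection
from citrusdet.yolo_io import GroundTruth
from citrusdet.metrics import (match_detections, precision_recall, average_precision,
                               mean_average_precision, map50, tide_errors, detection_tally)


def D(img, cls, box, conf):
    return Detection(img, cls, box, conf)


def G(img, cls, box):
    return GroundTruth(img, cls, box)


def _perfect(n=5):
    gts = [G(i, i % 3, (10, 10, 50, 50)) for i in range(n)]
    dets = [D(i, i % 3, (10, 10, 50, 50), 0.9) for i in range(n)]
    return dets, gts


class TestMatching:
    def test_perfect_detections_all_tp(self):
        dets, gts = _perfect()
        m = match_detections([dets[0]], [gts[0]], 0.5)
        assert m.tp == 1 and m.fp == 0 and m.fn == 0

    def test_wrong_class_is_fp_and_fn(self):
        m = match_detections([D(0, 1, (10, 10, 50, 50), 0.9)],
                             [G(0, 0, (10, 10, 50, 50))], 0.5)
        assert m.tp == 0 and m.fp == 1 and m.fn == 1

    def test_greedy_matches_best_iou_first(self):
        gts = [G(0, 0, (0, 0, 10, 10)), G(0, 0, (8, 0, 18, 10))]
        dets = [D(0, 0, (1, 0, 11, 10), 0.9), D(0, 0, (8, 0, 18, 10), 0.8)]
        m = match_detections(dets, gts, 0.5)
        assert m.det_flags == ["TP", "TP"]
        assert m.det_gt == [0, 1]

    def test_counts_reconcile_with_totals(self, rng):
        # TP+FP = detections, TP+FN = gts on random scenes
        for _ in range(20):
            gts = [G(0, int(rng.integers(0, 3)),
                     tuple(np.sort(rng.random(4) * 50).tolist())) for _ in range(4)]
            gts = [g for g in gts if g.box[2] > g.box[0] and g.box[3] > g.box[1]]
            dets = [D(0, int(rng.integers(0, 3)),
                      tuple((np.sort(rng.random(4) * 50) + [0, 0, 1, 1]).tolist()),
                      float(rng.random())) for _ in range(5)]
            m = match_detections(sorted(dets, key=lambda d: -d.confidence), gts, 0.5)
            assert m.tp + m.fp == len(dets)
            assert m.tp + m.fn == len(gts)


class TestPrecisionRecall:
    def test_direct_arithmetic(self):
        gts = [G(0, 0, (0, 0, 10, 10)), G(0, 0, (20, 0, 30, 10)),
               G(0, 0, (40, 0, 50, 10)), G(0, 0, (60, 0, 70, 10))]
        dets = [D(0, 0, (0, 0, 10, 10), 0.9), D(0, 0, (20, 0, 30, 10), 0.8),
                D(0, 0, (40, 0, 50, 10), 0.7), D(0, 1, (60, 0, 70, 10), 0.6)]
        m = match_detections(dets, gts, 0.5)
        p, r = precision_recall(m)
        assert p == 3 / 4 and r == 3 / 4

    def test_no_detections_convention(self):
        m = match_detections([], [G(0, 0, (0, 0, 10, 10))], 0.5)
        assert precision_recall(m) == (0.0, 0.0)


class TestAveragePrecision:
    def test_perfect_detector_is_100(self):
        dets, gts = _perfect(6)
        assert abs(map50(dets, gts, 6) - 100.0) < 1e-9

    def test_single_wrong_class_detection_ap_zero(self):
        gts = [G(0, 0, (10, 10, 50, 50))]
        dets = [D(0, 1, (10, 10, 50, 50), 0.9)]
        assert average_precision(dets, gts, 0, 0.5) == 0.0

    def test_class_without_gts_excluded_from_mean(self):
        dets, gts = _perfect(3)  # classes 0..2 only
        assert abs(mean_average_precision(dets, gts, 6) - 100.0) < 1e-9

    def test_against_exact_all_point_integration(self, rng):
        # small fixture; 101-point interpolation within 0.5 AP points of the
        # exact area under the interpolated-precision curve
        gts = [G(i, 0, (0, 0, 10, 10)) for i in range(8)]
        dets = []
        for i in range(8):
            good = i < 5
            box = (0, 0, 10, 10) if good else (40, 40, 50, 50)
            dets.append(D(i, 0, box, 0.9 - 0.05 * i))
        dets.append(D(0, 0, (41, 41, 51, 51), 0.95))  # early fp
        ap = average_precision(dets, gts, 0, 0.5)
        # exact: walk the PR curve point by point
        order = sorted(dets, key=lambda d: -d.confidence)
        matched = set()
        tps = []
        for d in order:
            hit = False
            for j, g in enumerate(gts):
                if j in matched or g.image_id != d.image_id:
                    continue
                if d.box == g.box:
                    matched.add(j)
                    hit = True
                    break
            tps.append(hit)
        tp = np.cumsum(tps)
        fp = np.cumsum([not t for t in tps])
        rec = tp / len(gts)
        prec = tp / (tp + fp)
        exact = 0.0
        prev_r = 0.0
        for k in range(len(order)):
            if tps[k]:
                exact += (rec[k] - prev_r) * prec[k:].max()
                prev_r = rec[k]
        assert abs(ap - exact) < 0.005

    def test_invariant_to_image_order_and_confidence_rescale(self):
        dets, gts = _perfect(5)
        base = map50(dets, gts, 6)
        shuffled = list(reversed(dets))
        assert map50(shuffled, gts, 6) == base
        rescaled = [D(d.image_id, d.class_id, d.box, d.confidence * 0.5) for d in dets]
        assert map50(rescaled, gts, 6) == base


class TestTide:
    def test_perfect_detections_zero_report(self):
        dets, gts = _perfect()
        r = tide_errors(dets, gts)
        assert (r.cls, r.loc, r.both, r.dupe, r.bkg, r.miss) == (0, 0, 0, 0, 0, 0)

    def test_wrong_class_high_iou_is_cls_error(self):
        r = tide_errors([D(0, 1, (10, 10, 50, 50), 0.9)],
                        [G(0, 0, (10, 10, 50, 50))])
        assert r.cls == 1 and r.loc == 0 and r.bkg == 0

    def test_duplicate_detection_counted_once(self):
        dets = [D(0, 0, (10, 10, 50, 50), 0.9), D(0, 0, (11, 11, 51, 51), 0.8)]
        r = tide_errors(dets, [G(0, 0, (10, 10, 50, 50))])
        assert r.dupe == 1 and r.fp == 1

    def test_background_far_box(self):
        dets = [D(0, 0, (10, 10, 50, 50), 0.9), D(0, 0, (200, 200, 220, 220), 0.8)]
        r = tide_errors(dets, [G(0, 0, (10, 10, 50, 50))])
        assert r.bkg == 1

    def test_loc_band_and_partition(self):
        # IoU ~0.23 same class -> Loc; wrong class same band -> Both
        dets = [D(0, 0, (0, 0, 10, 10), 0.9), D(1, 1, (0, 0, 10, 10), 0.9)]
        gts = [G(0, 0, (5, 0, 15, 10)), G(1, 0, (5, 0, 15, 10))]
        r = tide_errors(dets, gts)
        assert r.loc == 1 and r.both == 1
        assert r.fp == r.cls + r.loc + r.both + r.dupe + r.bkg

    def test_partition_reconciles_on_random_scenes(self, rng):
        dets, gts = [], []
        for img in range(12):
            for _ in range(int(rng.integers(0, 4))):
                x, y = rng.random(2) * 60
                gts.append(G(img, int(rng.integers(0, 3)), (x, y, x + 10 + rng.random() * 10, y + 10)))
            for _ in range(int(rng.integers(0, 5))):
                x, y = rng.random(2) * 60
                dets.append(D(img, int(rng.integers(0, 3)),
                              (x, y, x + 10 + rng.random() * 10, y + 10), float(rng.random())))
        r = tide_errors(dets, gts)
        assert r.fp == r.cls + r.loc + r.both + r.dupe + r.bkg
        assert 0 <= r.miss <= r.fn


class TestTally:
    def test_perfect_set(self):
        dets, gts = _perfect(7)
        assert detection_tally(dets, gts) == (7, 0, 0)

    def test_empty_detections(self):
        _, gts = _perfect(4)
        assert detection_tally([], gts) == (0, 4, 0)

    def test_twenty_image_fixture_matches_manual_count(self, rng):
        dets, gts = [], []
        want_right = want_miss = want_err = 0
        for img in range(20):
            gts.append(G(img, 0, (10, 10, 30, 30)))
            kind = img % 4
            if kind == 0:        # clean hit
                dets.append(D(img, 0, (11, 11, 31, 31), 0.9))
                want_right += 1
            elif kind == 1:      # miss
                want_miss += 1
            elif kind == 2:      # hit + spurious extra
                dets.append(D(img, 0, (10, 10, 30, 30), 0.9))
                dets.append(D(img, 0, (60, 60, 80, 80), 0.8))
                want_right += 1
                want_err += 1
            else:                # wrong class only
                dets.append(D(img, 1, (10, 10, 30, 30), 0.9))
                want_miss += 1
                want_err += 1
        assert detection_tally(dets, gts, 0.45) == (want_right, want_miss, want_err)
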