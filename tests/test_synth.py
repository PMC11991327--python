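"""Synthetic scene generator, label I/O, splitting, oversampling."""

import numpy as np
import pytest

from citrusdet.synth import (SceneSpec, LesionSpec, render_scene, random_scene_spec,
                             generate_dataset, split_dataset, oversample_class,
                             CLASS_NAMES, EASY_PALETTE)
from citrusdet.yolo_io import (GroundTruth, write_yolo_label, read_yolo_label)


class TestRenderScene:
    def test_empty_spec_gives_background_only(self):
        img, gts = render_scene(SceneSpec((64, 64), 0, []), seed=1)
        assert img.shape == (64, 64, 3) and gts == []

    def test_deterministic_bit_identical(self):
        spec = SceneSpec((96, 96), 3, [LesionSpec(2, (48, 48), 12)])
        a, ga = render_scene(spec, seed=9)
        b, gb = render_scene(spec, seed=9)
        assert np.array_equal(a, b)
        assert [g.box for g in ga] == [g.box for g in gb]

    def test_different_seed_differs(self):
        spec = SceneSpec((64, 64), 3, [LesionSpec(0, (32, 32), 10)])
        a, _ = render_scene(spec, seed=1)
        b, _ = render_scene(spec, seed=2)
        assert not np.array_equal(a, b)

    def test_out_of_bounds_lesion_rejected(self):
        spec = SceneSpec((64, 64), 0, [LesionSpec(0, (2, 2), 10)])
        with pytest.raises(ValueError):
            render_scene(spec, seed=0)

    def test_boxes_tight_and_inside(self, rng):
        for s in range(30):
            spec = random_scene_spec(np.random.default_rng(s), size=(96, 96))
            img, gts = render_scene(spec, seed=s)
            for g in gts:
                x1, y1, x2, y2 = g.box
                assert 0 <= x1 < x2 <= 96 and 0 <= y1 < y2 <= 96
                assert (x2 - x1) >= 2 and (y2 - y1) >= 2

    def test_easy_classes_color_separable(self):
        """Mean lesion color sits closer to its own palette entry than any other."""
        hits = 0
        total = 0
        for s in range(24):
            spec = random_scene_spec(np.random.default_rng(1000 + s), size=(96, 96),
                                     n_lesions=(1, 1), easy=True)
            img, gts = render_scene(spec, seed=s)
            g = gts[0]
            x1, y1, x2, y2 = (int(v) for v in g.box)
            patch = img[y1:y2, x1:x2].reshape(-1, 3).astype(float)
            # lesion pixels = quartile furthest from the background colour
            bg = np.median(img.reshape(-1, 3), axis=0)
            dist_bg = np.linalg.norm(patch - bg, axis=1)
            core = patch[dist_bg >= np.quantile(dist_bg, 0.75)]
            mean = core.mean(axis=0)
            dists = {k: np.linalg.norm(mean - np.array(v)) for k, v in EASY_PALETTE.items()}
            if min(dists, key=dists.get) == g.class_id:
                hits += 1
            total += 1
        assert hits / total >= 0.7


class TestYoloLabels:
    def test_full_image_box_line(self, tmp_path):
        p = tmp_path / "l.txt"
        write_yolo_label([GroundTruth(0, 3, (0, 0, 100, 80))], (100, 80), p)
        assert p.read_text().strip() == "3 0.500000 0.500000 1.000000 1.000000"

    def test_empty_list_empty_file(self, tmp_path):
        p = tmp_path / "l.txt"
        write_yolo_label([], (100, 80), p)
        assert p.read_text() == ""
        assert read_yolo_label(p, (100, 80)) == []

    def test_hundred_random_boxes_round_trip(self, rng, tmp_path):
        p = tmp_path / "l.txt"
        gts = []
        for _ in range(100):
            x1, y1 = rng.random(2) * 200
            w, h = rng.random(2) * 50 + 1
            gts.append(GroundTruth(0, int(rng.integers(0, 6)),
                                   (x1, y1, min(x1 + w, 256), min(y1 + h, 256))))
        write_yolo_label(gts, (256, 256), p)
        back = read_yolo_label(p, (256, 256))
        for a, b in zip(gts, back):
            assert a.class_id == b.class_id
            # 1e-6 in normalized units = 256e-6 px
            assert np.abs(np.array(a.box) - np.array(b.box)).max() <= 256 * 1e-6 + 1e-9

    def test_out_of_range_coordinate_reports_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.2\n1 1.5 0.5 0.2 0.2\n")
        with pytest.raises(ValueError, match=":2"):
            read_yolo_label(p, (100, 100))


class TestSplit:
    def _items(self, n, cls=0):
        return [{"image": f"i{cls}_{k}.png", "label": f"l{cls}_{k}.txt", "class": cls}
                for k in range(n)]

    def test_published_train_count_at_6050(self):
        m = split_dataset(self._items(6050), (8, 1, 1), seed=0)
        assert len(m.splits["train"]) == 4840

    def test_ten_items_split_8_1_1(self):
        m = split_dataset(self._items(10), (8, 1, 1), seed=0)
        assert {s: len(v) for s, v in m.splits.items()} == {"train": 8, "val": 1, "test": 1}

    def test_stratified_within_one_image_of_global_ratio(self):
        items = self._items(100, 0) + self._items(50, 1) + self._items(30, 2)
        m = split_dataset(items, (8, 1, 1), seed=3)
        for cls, n in ((0, 100), (1, 50), (2, 30)):
            n_train = sum(it["class"] == cls for it in m.splits["train"])
            assert abs(n_train - 0.8 * n) <= 1.0

    def test_deterministic_under_seed(self):
        items = self._items(40)
        a = split_dataset(items, seed=5)
        b = split_dataset(items, seed=5)
        assert [i["image"] for i in a.splits["train"]] == [i["image"] for i in b.splits["train"]]

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._items(10), (0, 0, 0))


class TestOversample:
    def test_expand_minority_and_label_validity(self, tmp_path):
        m = generate_dataset(tmp_path / "ds", 30, seed=4, size=(64, 64),
                             n_lesions=(1, 2))
        cls = m.splits["train"][0]["class"]
        have = sum(it["class"] == cls for it in m.splits["train"])
        target = have + 6
        m2 = oversample_class(m, cls, target, seed=1)
        got = [it for it in m2.splits["train"] if it["class"] == cls]
        assert len(got) == target
        for it in got:
            if it["origin"].startswith("aug"):
                gts = read_yolo_label(it["label"], (64, 64))
                for g in gts:
                    x1, y1, x2, y2 = g.box
                    assert -1e-6 <= x1 < x2 <= 64 + 1e-6
                    assert -1e-6 <= y1 < y2 <= 64 + 1e-6

    def test_target_at_current_count_is_noop(self, tmp_path):
        m = generate_dataset(tmp_path / "ds2", 12, seed=4, size=(64, 64))
        cls = m.splits["train"][0]["class"]
        have = sum(it["class"] == cls for it in m.splits["train"])
        m2 = oversample_class(m, cls, have, seed=1)
        assert m2.counts() == m.counts()


def test_generate_dataset_writes_consistent_manifest(tmp_path):
    m = generate_dataset(tmp_path / "d", 15, seed=7, size=(64, 64))
    assert sum(m.counts().values()) == 15
    assert (tmp_path / "d" / "data.yaml").exists()
    for it in m.all_items():
        assert it["image"].endswith(".png") and it["label"].endswith(".txt")
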