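"""Annotation I/O, tiling, augmentation, splitting, histograms."""

import numpy as np
import pytest

from spikenet.dataio import (AnnotationError, AnnotationRecord, SplitManifest,
                             augment, brightness_balance, channel_histograms,
                             expand_dataset, letterbox, read_rolabelimg, split,
                             tile, tile_record, write_rolabelimg)
from spikenet.rotgeom import OrientedBox, to_polygon
from spikenet.synthfield import SceneConfig, generate_scene

from conftest import random_box, rasterize_boxes


@pytest.fixture
def scene():
    _, rec = generate_scene(SceneConfig(seed=7))
    return rec


def boxes_close(a, b, tol=1e-6):
    assert len(a) == len(b)
    for x, y in zip(a, b):
        assert (y.cx, y.cy, y.w, y.h) == pytest.approx((x.cx, x.cy, x.w, x.h), abs=tol)
        d = abs(x.theta_deg - y.theta_deg) % 180
        assert min(d, 180 - d) < tol


class TestRoLabelImg:
    def test_round_trip(self, tmp_path, rng):
        rec = AnnotationRecord(
            image_id="img_0", stage="filling",
            boxes=[random_box(rng) for _ in range(6)])
        path = tmp_path / "img_0.xml"
        write_rolabelimg(rec, path, image_size=(150, 150))
        back = read_rolabelimg(path)
        assert back.image_id == "img_0" and back.stage == "filling"
        boxes_close(rec.boxes, back.boxes)

    def test_stored_geometry_preserved(self, tmp_path):
        """A stored box whose w-side (along the stored angle) is longer is
        normalized to the internal short/long convention with the same
        corner polygon."""
        xml = """<annotation><filename>t</filename>
        <object><name>spike</name><robndbox>
        <cx>50</cx><cy>40</cy><w>40</w><h>10</h><angle>0.0</angle>
        </robndbox></object></annotation>"""
        p = tmp_path / "t.xml"
        p.write_text(xml)
        b = read_rolabelimg(p).boxes[0]
        assert (b.w, b.h) == (10, 40)
        # stored 40-px side lies along angle 0 -> long side along x
        corners = to_polygon(b)
        assert corners[:, 0].max() - corners[:, 0].min() == pytest.approx(40)
        assert corners[:, 1].max() - corners[:, 1].min() == pytest.approx(10)

    def test_empty_object_list(self, tmp_path):
        p = tmp_path / "e.xml"
        p.write_text("<annotation><filename>e</filename></annotation>")
        rec = read_rolabelimg(p)
        assert rec.boxes == []

    def test_malformed_xml_reports_line(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<annotation>\n<object>\n")
        with pytest.raises(AnnotationError, match="line"):
            read_rolabelimg(p)

    def test_missing_field_named(self, tmp_path):
        p = tmp_path / "m.xml"
        p.write_text("""<annotation><filename>m</filename><object><name>s</name>
        <robndbox><cx>1</cx><cy>2</cy><w>3</w><h>4</h></robndbox>
        </object></annotation>""")
        with pytest.raises(AnnotationError, match="angle"):
            read_rolabelimg(p)


class TestTile:
    def test_coordinate_shift_single_box(self, rng):
        img = rng.integers(0, 255, (300, 300, 3), dtype=np.uint8)
        tiles, dropped = tile(img, [OrientedBox(75, 75, 4, 12, 30)])
        assert dropped == 0
        assert len(tiles[0][1]) == 1 and all(len(t[1]) == 0 for t in tiles[1:])
        b = tiles[0][1][0]
        assert (b.cx, b.cy) == (75, 75)

    def test_one_box_per_quadrant(self, rng):
        img = rng.integers(0, 255, (300, 300, 3), dtype=np.uint8)
        boxes = [OrientedBox(75, 75, 4, 12, 0), OrientedBox(225, 75, 4, 12, 0),
                 OrientedBox(75, 225, 4, 12, 0), OrientedBox(225, 225, 4, 12, 0)]
        tiles, _ = tile(img, boxes)
        assert [len(t[1]) for t in tiles] == [1, 1, 1, 1]

    def test_boundary_box_goes_right(self, rng):
        img = rng.integers(0, 255, (300, 300, 3), dtype=np.uint8)
        tiles, _ = tile(img, [OrientedBox(150.0, 40, 4, 12, 0)])
        assert len(tiles[1][1]) == 1  # half-open rule: x = 150 -> right tile
        assert tiles[1][1][0].cx == 0.0

    def test_center_crop_larger_image(self, rng):
        img = rng.integers(0, 255, (320, 340, 3), dtype=np.uint8)
        # center crop removes 10 rows top, 20 cols left
        tiles, dropped = tile(img, [OrientedBox(5, 30, 4, 12, 0),
                                    OrientedBox(120, 120, 4, 12, 0)])
        assert dropped == 1
        b = tiles[0][1][0]
        assert (b.cx, b.cy) == (100, 110)

    def test_too_small_raises(self, rng):
        with pytest.raises(ValueError):
            tile(np.zeros((200, 300, 3), dtype=np.uint8), [])

    def test_tile_record_ids(self, rng):
        img = rng.integers(0, 255, (300, 300, 3), dtype=np.uint8)
        rec = AnnotationRecord(image_id="uav1", boxes=[], image=img)
        out, _ = tile_record(rec)
        assert [r.image_id for r in out] == [f"uav1__t{k}" for k in range(4)]


class TestAugment:
    @pytest.mark.parametrize("op", ["hflip", "vflip", "rot180"])
    def test_involution(self, scene, op):
        twice = augment(augment(scene, op), op)
        assert np.array_equal(twice.image, scene.image)
        boxes_close(scene.boxes, twice.boxes)

    def test_rot90_four_times_identity(self, scene):
        r = scene
        for _ in range(4):
            r = augment(r, "rot90")
        assert np.array_equal(r.image, scene.image)
        boxes_close(scene.boxes, r.boxes)

    def test_rot90_rot270_inverse(self, scene):
        r = augment(augment(scene, "rot90"), "rot270")
        assert np.array_equal(r.image, scene.image)
        boxes_close(scene.boxes, r.boxes)

    @pytest.mark.parametrize("op", ["hflip", "vflip", "rot90", "rot180", "rot270"])
    def test_mask_commutation_oracle(self, scene, op):
        """Transforming the rasterized box mask like the pixels equals
        rasterizing the transformed boxes."""
        S = scene.image.shape[0]
        m = rasterize_boxes(scene.boxes, S)
        pixel_like = {
            "hflip": lambda a: a[:, ::-1], "vflip": lambda a: a[::-1],
            "rot90": lambda a: np.rot90(a, k=-1), "rot180": lambda a: a[::-1, ::-1],
            "rot270": lambda a: np.rot90(a, k=1)}[op]
        out = augment(scene, op)
        assert np.array_equal(pixel_like(m), rasterize_boxes(out.boxes, S))

    def test_box_count_and_bounds_preserved(self, scene):
        S = scene.image.shape[0]
        for op in ("hflip", "vflip", "rot90", "rot180", "rot270"):
            out = augment(scene, op)
            assert len(out.boxes) == len(scene.boxes)
            for b in out.boxes:
                assert 0 <= b.cx <= S and 0 <= b.cy <= S

    def test_brightness_scales_and_keeps_boxes(self, scene):
        out = augment(scene, "brightness", scale=0.5)
        assert out.image.mean() == pytest.approx(
            np.clip(scene.image * 0.5, 0, 255).astype(np.uint8).mean(), abs=1e-9)
        boxes_close(scene.boxes, out.boxes)

    def test_unknown_op_rejected(self, scene):
        with pytest.raises(ValueError, match="unknown augmentation"):
            augment(scene, "zoom")

    def test_stage_tag_preserved(self, scene):
        assert augment(scene, "hflip").stage == scene.stage


class TestExpand:
    def test_eightfold_cardinality(self, scene):
        out = expand_dataset([scene])
        assert len(out) == 8
        assert all(r.source_id == scene.image_id for r in out)

    def test_variants_pairwise_distinct(self, scene):
        imgs = [r.image.tobytes() for r in expand_dataset([scene])]
        assert len(set(imgs)) == 8

    def test_brightness_balance_applied(self, scene):
        for r in expand_dataset([scene], balance_target=128.0):
            assert abs(r.image.mean() - 128.0) < 2.0  # clamping may shift slightly

    def test_balance_uniform_image(self):
        img = np.full((10, 10, 3), 60, dtype=np.uint8)
        out = brightness_balance(img, 128.0)
        assert np.all(out == 128)


class TestSplit:
    def _records(self, n):
        return [AnnotationRecord(image_id=f"r{i:03d}", boxes=[]) for i in range(n)]

    def test_exact_ratio_on_singletons(self):
        m = split(self._records(100), seed=3)
        assert (len(m.train), len(m.val), len(m.test)) == (70, 20, 10)

    def test_deterministic(self):
        a = split(self._records(50), seed=9)
        b = split(self._records(50), seed=9)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)

    def test_different_seed_differs(self):
        a = split(self._records(50), seed=1)
        b = split(self._records(50), seed=2)
        assert a.train != b.train

    def test_partitions_disjoint_and_complete(self):
        m = split(self._records(47), seed=5)
        all_ids = m.train + m.val + m.test
        assert len(all_ids) == 47 and len(set(all_ids)) == 47

    def test_augmented_variants_stay_together(self, scene):
        sources = []
        for i in range(10):
            _, rec = generate_scene(SceneConfig(seed=i))
            rec.image_id = rec.source_id = f"s{i}"
            sources.append(rec)
        recs = expand_dataset(sources)
        m = split(recs, seed=11)
        part = m.partition_of()
        for r in recs:
            group = {part[x.image_id] for x in recs if x.source_id == r.source_id}
            assert len(group) == 1
        assert (len(m.train), len(m.val), len(m.test)) == (56, 16, 8)

    def test_manifest_file_round_trip(self, tmp_path):
        m = split(self._records(20), seed=2)
        p = tmp_path / "manifest.tsv"
        m.save(p)
        back = SplitManifest.load(p)
        assert back.seed == 2
        assert (back.train, back.val, back.test) == (m.train, m.val, m.test)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split(self._records(5), seed=0)


class TestHistogramsAndLetterbox:
    def test_uniform_gray_single_bin(self):
        img = np.full((8, 8, 3), 128, dtype=np.uint8)
        h = channel_histograms([img])
        assert np.all(h[:, 128] == 64)
        assert h.sum() == 3 * 64

    def test_stage_histograms_show_red_shift(self):
        """Maturity scenes put their red-band mass at higher bins than
        filling scenes (the generator's palette contrast)."""
        from spikenet.synthfield import SceneConfig, generate_scene

        filling = [generate_scene(SceneConfig(stage="filling", seed=i))[0]
                   for i in range(4)]
        maturity = [generate_scene(SceneConfig(stage="maturity", seed=i))[0]
                    for i in range(4)]
        bins = np.arange(256)

        def red_mean_bin(imgs):
            h = channel_histograms(imgs)[0]
            return (h * bins).sum() / h.sum()

        assert red_mean_bin(maturity) > red_mean_bin(filling) + 20

    def test_total_count_conservation(self, rng):
        imgs = [rng.integers(0, 256, (20, 30, 3), dtype=np.uint8) for _ in range(4)]
        h = channel_histograms(imgs)
        assert np.all(h.sum(axis=1) == 4 * 20 * 30)

    def test_letterbox_pads_and_shifts(self, rng):
        img = rng.integers(0, 255, (150, 150, 3), dtype=np.uint8)
        boxes = [OrientedBox(10, 20, 4, 12, 15)]
        out, shifted, (px, py) = letterbox(img, boxes, size=160)
        assert out.shape == (160, 160, 3) and (px, py) == (5, 5)
        assert (shifted[0].cx, shifted[0].cy) == (15, 25)
        assert np.array_equal(out[5:155, 5:155], img)
        assert np.all(out[:5] == 114)

    def test_letterbox_too_large(self, rng):
        with pytest.raises(ValueError):
            letterbox(np.zeros((200, 200, 3), dtype=np.uint8), [], size=160)
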