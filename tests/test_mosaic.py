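import numpy as np
import pytest

import roimosaic as rm
from roimosaic.mosaic import annotation_frame


def _flat(image_id, label, size=(100, 100), box=rm.RoiBox(10, 10, 20, 20)):
    return rm.AnnotatedImage(
        image_id, np.full(size, 0.5), [box.with_label(label)], label
    )


class TestBalanceClasses:
    def test_counts_equalized_and_larger_class_untouched(self):
        imgs = [_flat(f"b{i}", "benign") for i in range(3)]
        imgs += [_flat(f"m{i}", "malignant") for i in range(5)]
        out = rm.balance_classes(imgs, seed=0)
        labels = [im.diagnosis for im in out]
        assert labels.count("benign") == labels.count("malignant") == 5
        assert out[: len(imgs)] == imgs  # originals preserved in order

    def test_already_balanced_is_identity(self):
        imgs = [_flat(f"b{i}", "benign") for i in range(4)]
        imgs += [_flat(f"m{i}", "malignant") for i in range(4)]
        assert rm.balance_classes(imgs, seed=7) == imgs

    def test_deterministic_given_seed(self):
        imgs = [_flat("b0", "benign")] + [_flat(f"m{i}", "malignant") for i in range(4)]
        a = [im.image_id for im in rm.balance_classes(imgs, seed=9)]
        b = [im.image_id for im in rm.balance_classes(imgs, seed=9)]
        assert a == b

    def test_missing_class_named_in_error(self):
        with pytest.raises(ValueError, match="malignant"):
            rm.balance_classes([_flat("b0", "benign")], seed=0)


class TestHarmonizeTile:
    def test_downscale_halves_box(self):
        tile = rm.harmonize_tile(_flat("a", "benign"), 50, 50)
        assert tile.image.rois[0] == rm.RoiBox(5, 5, 10, 10, "benign")
        # rasterized overlap of the scaled box with the scaled support is exact
        assert (tile.sx, tile.sy) == (0.5, 0.5)

    def test_tile_sized_image_is_identity(self):
        src = _flat("a", "benign", size=(50, 50))
        tile = rm.harmonize_tile(src, 50, 50)
        assert np.array_equal(tile.image.pixels, src.pixels)
        assert tile.image.rois == src.rois

    def test_wide_image_padded_vertically(self):
        src = _flat("a", "benign", size=(100, 200))  # rows x cols
        tile = rm.harmonize_tile(src, 100, 100)
        assert (tile.sx, tile.sy) == (0.5, 0.5)
        assert (tile.pad_left, tile.pad_top) == (0, 25)
        assert tile.image.rois[0] == rm.RoiBox(5, 30, 10, 10, "benign")
        # padding is background 0 above and below the resized content
        assert tile.image.pixels[:25].max() == 0 and tile.image.pixels[-25:].max() == 0

    def test_collapsing_roi_suggests_larger_tile(self):
        src = _flat("a", "benign", size=(100, 100), box=rm.RoiBox(0, 0, 2, 2))
        with pytest.raises(ValueError, match="larger tile"):
            rm.harmonize_tile(src, 8, 8)


class TestBuild2x2:
    def test_boxes_shifted_by_cell_offsets(self, tile_sized_sources, layout_2x2):
        benign, malignant = tile_sized_sources
        comp = rm.build_2x2(benign, malignant, layout_2x2)
        corners = sorted((b.x, b.y) for b in comp.rois)
        assert corners == [(10, 10), (10, 138), (138, 10), (138, 138)]
        assert all(b.w == 20 and b.h == 20 for b in comp.rois)
        # default placement: benign on the diagonal
        by_cell = {p.cell: p.label for p in comp.provenance}
        assert by_cell == {
            (1, 1): "benign", (2, 2): "benign", (1, 2): "malignant", (2, 1): "malignant"
        }

    def test_label_slot_mismatch_names_cell(self, tile_sized_sources, layout_2x2):
        benign, malignant = tile_sized_sources
        with pytest.raises(ValueError, match=r"\(1, 1\).*benign"):
            rm.build_2x2([malignant[0], benign[1]], [benign[0], malignant[1]], layout_2x2)

    def test_translation_preserves_total_roi_area(self, tile_sized_sources, layout_2x2):
        benign, malignant = tile_sized_sources
        comp = rm.build_2x2(benign, malignant, layout_2x2)
        shape = comp.pixels.shape
        total = sum(rm.box_to_mask(b, shape).sum() for b in comp.rois)
        assert total == 4 * 20 * 20


class TestBuild1x2:
    def test_right_tile_box_shifted_by_tile_width(self, tile_sized_sources):
        benign, malignant = tile_sized_sources
        comp = rm.build_1x2(benign[0], malignant[0])
        assert comp.pixels.shape == (128, 256)
        assert {(b.x, b.label) for b in comp.rois} == {(10, "benign"), (138, "malignant")}

    def test_swapped_layout_exchanges_offsets(self, tile_sized_sources):
        benign, malignant = tile_sized_sources
        swapped = rm.MosaicLayout(
            "one_by_two", 128, 128, {(1, 1): "malignant", (1, 2): "benign"}
        )
        comp = rm.build_1x2(benign[0], malignant[0], swapped)
        assert {(b.x, b.label) for b in comp.rois} == {(10, "malignant"), (138, "benign")}


class TestRotationalArrangements:
    def test_three_arrangements_with_distinct_placements(self, tile_sized_sources, layout_2x2):
        benign, malignant = tile_sized_sources
        comp = rm.build_2x2(benign, malignant, layout_2x2)
        rots = rm.rotational_arrangements(comp)
        assert len(rots) == 3
        placements = [tuple(sorted((p.cell, p.image_id) for p in c.provenance))
                      for c in [comp] + rots]
        assert len(set(placements)) == 4
        for c in rots:
            labels = sorted(b.label for b in c.rois)
            assert labels == ["benign", "benign", "malignant", "malignant"]

    def test_180_moves_each_tile_across_the_diagonal(self, tile_sized_sources, layout_2x2):
        benign, malignant = tile_sized_sources
        comp = rm.build_2x2(benign, malignant, layout_2x2)
        rot180 = rm.rotational_arrangements(comp)[1]
        moved = {p.image_id: p.cell for p in rot180.provenance}
        orig = {p.image_id: p.cell for p in comp.provenance}
        diag = {(1, 1): (2, 2), (2, 2): (1, 1), (1, 2): (2, 1), (2, 1): (1, 2)}
        assert moved == {iid: diag[cell] for iid, cell in orig.items()}
        # boxes are pure translations of the originals
        for p, p0 in zip(rot180.provenance, comp.provenance):
            assert p.tile_box == p0.tile_box

    def test_quadrant_permutation_has_order_four(self, tile_sized_sources, layout_2x2):
        benign, malignant = tile_sized_sources
        comp = rm.build_2x2(benign, malignant, layout_2x2)
        current = comp
        for _ in range(4):
            current = rm.rotational_arrangements(current)[0]
        assert np.array_equal(current.pixels, comp.pixels)
        assert [p.cell for p in current.provenance] == [p.cell for p in comp.provenance]

    def test_pixel_mode_boxes_track_rotated_raster(self, tile_sized_sources, layout_2x2):
        benign, malignant = tile_sized_sources
        # make tiles distinguishable by marking each ROI region
        comp = rm.build_2x2(benign, malignant, layout_2x2)
        for rot, k in zip(rm.rotational_arrangements(comp, mode="pixels"), (1, 2, 3)):
            expected = np.rot90(comp.pixels, k=-k)
            assert np.array_equal(rot.pixels, expected)
            for b0, b in zip(comp.rois, rot.rois):
                m = rm.box_to_mask(b0, comp.pixels.shape)
                assert np.array_equal(rm.box_to_mask(b, rot.pixels.shape), np.rot90(m, k=-k))

    def test_unsupported_for_1x2(self, tile_sized_sources):
        benign, malignant = tile_sized_sources
        comp = rm.build_1x2(benign[0], malignant[0])
        with pytest.raises(ValueError, match="2x2"):
            rm.rotational_arrangements(comp)


class TestBuildDataset:
    def test_counts_with_and_without_rotations(self, tile_sized_sources, layout_2x2):
        benign, malignant = tile_sized_sources
        comps, ann = rm.build_dataset(benign + malignant, layout_2x2, seed=1)
        assert len(comps) == 4 and len(ann) == 16
        comps2, ann2 = rm.build_dataset(
            benign + malignant, layout_2x2, seed=1, include_rotations=False
        )
        assert len(comps2) == 1 and len(ann2) == 4

    def test_same_seed_gives_identical_annotations(self, easy_images, layout_2x2):
        _, a = rm.build_dataset(easy_images, layout_2x2, seed=5)
        _, b = rm.build_dataset(easy_images, layout_2x2, seed=5)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_insufficient_images_error_reports_counts(self, tile_sized_sources, layout_2x2):
        benign, malignant = tile_sized_sources
        with pytest.raises(ValueError, match="1 benign"):
            rm.build_dataset([benign[0], malignant[0]], layout_2x2, seed=0, balance=False)


def test_provenance_round_trip_recovers_source_boxes(easy_images, layout_2x2):
    """Inverting recorded pad + scale recovers the original box within 1 px."""
    comps, _ = rm.build_dataset(easy_images, layout_2x2, seed=2, include_rotations=True)
    for comp in comps:
        for prov in comp.provenance:
            rec = prov.recover_source_box()
            src = prov.source_box
            err = max(
                abs(rec.x - src.x), abs(rec.y - src.y), abs(rec.w - src.w), abs(rec.h - src.h)
            )
            tol = 0 if (prov.sx, prov.sy) == (1.0, 1.0) else 1
            assert err <= tol
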