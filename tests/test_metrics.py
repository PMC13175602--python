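import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import roimosaic as rm
from roimosaic.geometry import ShapeMismatchError
from roimosaic.metrics import OverlapTriple

boxes = st.builds(
    rm.RoiBox,
    x=st.integers(0, 20), y=st.integers(0, 20),
    w=st.integers(1, 10), h=st.integers(1, 10),
)


def closed_form_triple(a: rm.RoiBox, b: rm.RoiBox):
    """Independent oracle: rectangle-arithmetic IoU/IoR/IoD in percent."""
    iw = max(0, min(a.x2, b.x2) - max(a.x, b.x))
    ih = max(0, min(a.y2, b.y2) - max(a.y, b.y))
    i = iw * ih
    u = a.area + b.area - i
    if b.area == 0:
        return 0.0, 0.0, 0.0
    return 100.0 * i / u, 100.0 * i / a.area, 100.0 * i / b.area


class TestOverlap:
    def test_identical_masks_score_100(self):
        m = rm.box_to_mask(rm.RoiBox(2, 3, 5, 7), (20, 20))
        t = rm.overlap(m, m)
        assert (t.iou, t.ior, t.iod) == (100.0, 100.0, 100.0)

    def test_disjoint_masks_score_0(self):
        r = rm.box_to_mask(rm.RoiBox(0, 0, 5, 5), (20, 20))
        d = rm.box_to_mask(rm.RoiBox(10, 10, 5, 5), (20, 20))
        t = rm.overlap(r, d)
        assert (t.iou, t.ior, t.iod) == (0.0, 0.0, 0.0)

    def test_half_overlap_brute_force(self):
        # I = 50, U = 150 by direct pixel count
        r = rm.box_to_mask(rm.RoiBox(0, 0, 10, 10), (20, 20))
        d = rm.box_to_mask(rm.RoiBox(5, 0, 10, 10), (20, 20))
        t = rm.overlap(r, d)
        assert t.iou == pytest.approx(100 * 50 / 150)
        assert t.ior == pytest.approx(50.0)
        assert t.iod == pytest.approx(50.0)

    def test_empty_detection_flagged_all_zero(self):
        r = rm.box_to_mask(rm.RoiBox(0, 0, 5, 5), (10, 10))
        t = rm.overlap(r, np.zeros((10, 10), bool))
        assert t.empty_detection and (t.iou, t.ior, t.iod) == (0.0, 0.0, 0.0)

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            rm.overlap(np.zeros((5, 5), bool), np.ones((5, 5), bool))

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            rm.overlap(np.ones((5, 5), bool), np.ones((6, 6), bool))

    def test_reported_worked_example_is_internally_consistent(self):
        """A published attention-map case (IoU 33.80, IoR 85.82, IoD 35.80):
        ordering bound and harmonic identity hold to rounding."""
        iou, ior, iod = 33.80, 85.82, 35.80
        assert 0 <= iou <= min(ior, iod) <= 100
        lhs = 1 / (iou / 100)
        rhs = 1 / (ior / 100) + 1 / (iod / 100) - 1
        assert lhs == pytest.approx(rhs, abs=5e-3)

    @given(a=boxes, b=boxes)
    @settings(max_examples=200, derandomize=True)
    def test_matches_closed_form_rectangle_arithmetic(self, a, b):
        shape = (32, 32)
        t = rm.overlap(rm.box_to_mask(a, shape), rm.box_to_mask(b, shape))
        iou, ior, iod = closed_form_triple(a, b)
        assert t.iou == pytest.approx(iou)
        assert t.ior == pytest.approx(ior)
        assert t.iod == pytest.approx(iod)
        t.check_consistency()

    @given(a=boxes, b=boxes)
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_swapping_masks_swaps_ior_iod(self, a, b):
        shape = (32, 32)
        ma, mb = rm.box_to_mask(a, shape), rm.box_to_mask(b, shape)
        t1, t2 = rm.overlap(ma, mb), rm.overlap(mb, ma)
        if not (t1.empty_detection or t2.empty_detection):
            assert t1.iou == pytest.approx(t2.iou)
            assert t1.ior == pytest.approx(t2.iod)
            assert t1.iod == pytest.approx(t2.ior)


def _triple(iou, ior, iod):
    return OverlapTriple(iou, ior, iod, area_r=100, area_d=100, area_i=int(iou))


class TestDatasetMean:
    def test_singleton_is_identity(self):
        t = _triple(33.33, 50.0, 50.0)
        assert rm.dataset_mean([t]).iou == t.iou

    def test_mean_of_extremes(self):
        m = rm.dataset_mean([_triple(0, 0, 0), _triple(100, 100, 100)])
        assert (m.iou, m.ior, m.iod) == (50.0, 50.0, 50.0)

    def test_mean_of_copies_is_the_copy(self):
        t = _triple(40.0, 60.0, 55.0)
        m = rm.dataset_mean([t] * 7)
        assert (m.iou, m.ior, m.iod) == (t.iou, t.ior, t.iod)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            rm.dataset_mean([])


class TestLocalizedFraction:
    def test_all_tp_localized(self):
        recs = [(_triple(100, 100, 100), "malignant", "malignant")] * 3
        out = rm.localized_fraction(recs, 30)
        assert out.tp_fraction == 1.0 and out.tp_total == 3

    def test_iou_exactly_at_threshold_counts(self):
        recs = [(_triple(30.0, 40, 40), "malignant", "malignant")]
        assert rm.localized_fraction(recs, 30).tp_fraction == 1.0

    def test_mixed_tp_set(self):
        recs = [
            (_triple(v, v, v), "malignant", "malignant") for v in (10.0, 30.0, 90.0)
        ]
        assert rm.localized_fraction(recs, 30).tp_fraction == pytest.approx(2 / 3)

    def test_absent_class_is_undefined_not_zero(self):
        recs = [(_triple(50, 50, 50), "malignant", "malignant")]
        out = rm.localized_fraction(recs, 30)
        assert out.tn_fraction is None and out.tn_total == 0

    def test_misclassified_records_excluded(self):
        recs = [
            (_triple(90, 90, 90), "benign", "malignant"),  # FN: not counted
            (_triple(90, 90, 90), "malignant", "malignant"),
        ]
        out = rm.localized_fraction(recs, 30)
        assert out.tp_total == 1 and out.tp_fraction == 1.0
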