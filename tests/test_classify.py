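import numpy as np
import pytest

import roimosaic as rm
from roimosaic.classify import ABSTAIN, EpochSeries
from roimosaic.detector import DetectionResult


class TestRates:
    def test_reference_confusion_counts(self):
        """Counts reconstructed from a reported test split (539 malignant /
        95 benign) at sensitivity 0.8646 and specificity 0.8000 reproduce
        the reported accuracy 0.8549 by direct formula evaluation."""
        r = rm.rates(rm.ConfusionCounts(tp=466, fn=73, tn=76, fp=19))
        assert r.accuracy == pytest.approx(0.8549)
        assert r.sensitivity == pytest.approx(0.8646)
        assert r.specificity == pytest.approx(0.8000)

    def test_zero_denominator_is_undefined_not_zero(self):
        r = rm.rates(rm.ConfusionCounts(tp=5, fn=0, tn=0, fp=0))
        assert r.accuracy == 1.0 and r.sensitivity == 1.0 and r.specificity is None

    def test_all_counts_equal_gives_half_accuracy(self):
        r = rm.rates(rm.ConfusionCounts(tp=3, fn=3, tn=3, fp=3))
        assert r.accuracy == 0.5

    def test_accuracy_is_prevalence_weighted_mix_of_sens_spec(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fn, tn, fp = rng.integers(1, 50, size=4)
            c = rm.ConfusionCounts(tp=int(tp), fn=int(fn), tn=int(tn), fp=int(fp))
            r = rm.rates(c, ndigits=12)
            pos, neg = tp + fn, tn + fp
            mix = (pos * r.sensitivity + neg * r.specificity) / (pos + neg)
            assert r.accuracy == pytest.approx(mix, abs=1e-9)

    def test_rates_round_trip_from_sens_spec_and_class_sizes(self):
        # reconstructing counts from (sens, spec, n_pos, n_neg) reproduces the rates
        sens, spec, n_pos, n_neg = 0.8646, 0.8000, 539, 95
        tp = round(sens * n_pos)
        tn = round(spec * n_neg)
        r = rm.rates(rm.ConfusionCounts(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn))
        assert r.sensitivity == pytest.approx(sens, abs=5e-4)
        assert r.specificity == pytest.approx(spec, abs=5e-4)


def _det(cells, tile=128):
    """Detections centered in given (row, col) cells with (label, conf)."""
    boxes = []
    for (row, col), label, conf in cells:
        x = (col - 1) * tile + tile // 2 - 5
        y = (row - 1) * tile + tile // 2 - 5
        boxes.append((rm.RoiBox(x, y, 10, 10, label), conf))
    return DetectionResult("comp", boxes)


class TestAnchorAggregation:
    def test_single_detection_in_anchor_cell(self, layout_2x2):
        dets = _det([((1, 1), "benign", 0.7)])
        out = rm.aggregate_anchor_cell(dets, layout_2x2)
        assert out.label == "benign" and not out.used_fallback

    def test_only_anchor_cell_matters(self, layout_2x2):
        dets = _det(
            [((1, 1), "benign", 0.2), ((1, 2), "malignant", 0.9),
             ((2, 1), "malignant", 0.9), ((2, 2), "malignant", 0.9)]
        )
        assert rm.aggregate_anchor_cell(dets, layout_2x2).label == "benign"

    def test_highest_confidence_wins_within_anchor(self, layout_2x2):
        dets = _det([((1, 1), "malignant", 0.9), ((1, 1), "benign", 0.4)])
        assert rm.aggregate_anchor_cell(dets, layout_2x2).label == "malignant"

    def test_empty_anchor_falls_back_to_vote_with_flag(self, layout_2x2):
        dets = _det([((2, 2), "benign", 0.9)])
        out = rm.aggregate_anchor_cell(dets, layout_2x2)
        assert out.label == "benign" and out.used_fallback

    def test_no_detections_abstain(self, layout_2x2):
        out = rm.aggregate_anchor_cell(DetectionResult("comp", []), layout_2x2)
        assert out.label == ABSTAIN


class TestVoteAggregation:
    def test_majority_of_equal_confidences(self):
        dets = _det(
            [((1, 1), "malignant", 0.5), ((1, 2), "malignant", 0.5),
             ((2, 1), "malignant", 0.5), ((2, 2), "benign", 0.5)]
        )
        assert rm.aggregate_vote(dets).label == "malignant"

    def test_single_region_returns_its_label(self):
        assert rm.aggregate_vote(_det([((2, 1), "benign", 0.6)])).label == "benign"

    def test_exact_tie_goes_to_malignant(self):
        dets = _det([((1, 1), "benign", 0.5), ((1, 2), "malignant", 0.5)])
        assert rm.aggregate_vote(dets).label == "malignant"

    def test_permutation_invariant(self):
        cells = [((1, 1), "benign", 0.9), ((1, 2), "malignant", 0.5), ((2, 1), "malignant", 0.3)]
        a = rm.aggregate_vote(_det(cells)).label
        b = rm.aggregate_vote(_det(cells[::-1])).label
        assert a == b

    def test_empty_abstains(self):
        assert rm.aggregate_vote(DetectionResult("c", [])).label == ABSTAIN


class TestEpochWindowStats:
    def test_constant_series_has_zero_std(self):
        s = EpochSeries(list(range(1, 11)), [0.8] * 10)
        out = rm.epoch_window_stats(s, (1, 10))
        assert out.mean == 0.8 and out.std == 0.0

    def test_two_values_sample_std(self):
        s = EpochSeries([31, 32], [0.8, 0.9])
        out = rm.epoch_window_stats(s, (31, 32))
        assert out.mean == pytest.approx(0.85)
        assert out.std == pytest.approx(0.0707, abs=5e-5)

    def test_window_of_length_one_flags_undefined_std(self):
        out = rm.epoch_window_stats(EpochSeries([5], [0.7]), (5, 5))
        assert out.mean == 0.7 and out.std == 0.0 and not out.std_defined

    def test_window_outside_series_raises(self):
        with pytest.raises(ValueError, match="missing"):
            rm.epoch_window_stats(EpochSeries([1, 2, 3], [0.1, 0.2, 0.3]), (2, 5))
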