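"""Classification metrics, region-to-image aggregation, and epoch-window reporting.

Malignant is the positive class throughout. Two aggregation rules turn the
per-region labels of a detector run on a 2x2 composite into a single
image-level label:

* **anchor**: use the label of the highest-confidence detection whose box
  center falls in grid cell (1,1); if that cell is empty, fall back to the
  vote rule (flagged).
* **vote**: confidence-weighted majority over all detected regions; an
  exact tie goes to malignant (the sensitivity-favoring choice, mirroring
  the clinical cost asymmetry).

Epoch-window reporting averages a per-epoch metric series over a stated
window (e.g. the last ten epochs of a run) and reports mean +/- sample
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import BENIGN, MALIGNANT
from .mosaic import MosaicLayout

ABSTAIN = "abstain"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies with malignant as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, predicted: Sequence[str], gold: Sequence[str]) -> "ConfusionCounts":
        if len(predicted) != len(gold):
            raise ValueError("predicted and gold label lists differ in length")
        tp = fp = tn = fn = 0
        for p, g in zip(predicted, gold):
            if g == MALIGNANT:
                tp += p == MALIGNANT
                fn += p != MALIGNANT
            elif g == BENIGN:
                tn += p == BENIGN
                fp += p != BENIGN
            else:
                raise ValueError(f"gold label must be benign/malignant, got {g!r}")
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class ClassificationRates:
    """Accuracy, sensitivity, specificity; None where the denominator is zero."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]


def rates(c: ConfusionCounts, ndigits: int = 4) -> ClassificationRates:
    """Accuracy = (TP+TN)/all, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

    Rates are reported rounded to ``ndigits`` decimals; a rate whose
    denominator is zero is undefined (None), never 0.
    """

    def _rate(num: int, den: int) -> Optional[float]:
        return round(num / den, ndigits) if den else None

    return ClassificationRates(
        accuracy=_rate(c.tp + c.tn, c.total),
        sensitivity=_rate(c.tp, c.tp + c.fn),
        specificity=_rate(c.tn, c.tn + c.fp),
    )


@dataclass(frozen=True)
class AggregationOutcome:
    """Image-level label plus how it was reached."""

    label: str  # benign | malignant | abstain
    used_fallback: bool = False


def aggregate_vote(dets) -> AggregationOutcome:
    """Confidence-weighted majority over all detected regions; ties -> malignant."""
    if not dets.boxes:
        return AggregationOutcome(ABSTAIN)
    weight: Dict[str, float] = {BENIGN: 0.0, MALIGNANT: 0.0}
    for box, conf in dets.boxes:
        if box.label not in weight:
            raise ValueError(f"detection box has no benign/malignant label: {box}")
        weight[box.label] += conf
    label = MALIGNANT if weight[MALIGNANT] >= weight[BENIGN] else BENIGN
    return AggregationOutcome(label)


def aggregate_anchor_cell(dets, layout: MosaicLayout) -> AggregationOutcome:
    """Label of the highest-confidence detection in grid cell (1,1).

    Detections are assigned to cells by box-center membership (boundary
    ties to the lower-index cell). With no detection in (1,1) the vote rule
    decides, flagged as a fallback; with no detections at all the outcome
    abstains.
    """
    if not dets.boxes:
        return AggregationOutcome(ABSTAIN)
    anchor = [
        (box, conf)
        for box, conf in dets.boxes
        if layout.cell_of_point(*box.center) == (1, 1)
    ]
    if not anchor:
        vote = aggregate_vote(dets)
        return AggregationOutcome(vote.label, used_fallback=True)
    best_box, _ = max(anchor, key=lambda bc: bc[1])
    return AggregationOutcome(best_box.label)


@dataclass
class EpochSeries:
    """Per-epoch values of one classification metric."""

    epochs: List[int]
    values: List[float]

    def __post_init__(self) -> None:
        if len(self.epochs) != len(self.values):
            raise ValueError("epochs and values differ in length")
        if len(set(self.epochs)) != len(self.epochs):
            raise ValueError("duplicate epoch indices")


@dataclass(frozen=True)
class WindowStats:
    mean: float
    std: float
    n: int
    std_defined: bool = True


def epoch_window_stats(series: EpochSeries, window: Tuple[int, int]) -> WindowStats:
    """Mean and sample (n-1) standard deviation over an inclusive epoch window.

    A window of length 1 has an undefined sample std; it is reported as 0
    with ``std_defined=False``. A window reaching outside the series raises.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty epoch window {window}")
    have = set(series.epochs)
    missing = [e for e in range(lo, hi + 1) if e not in have]
    if missing:
        raise ValueError(f"epoch window {window} not fully covered by series: missing {missing}")
    vals = [v for e, v in zip(series.epochs, series.values) if lo <= e <= hi]
    arr = np.asarray(vals, dtype=float)
    if arr.size == 1:
        return WindowStats(mean=float(arr[0]), std=0.0, n=1, std_defined=False)
    return WindowStats(mean=float(arr.mean()), std=float(arr.std(ddof=1)), n=int(arr.size))
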