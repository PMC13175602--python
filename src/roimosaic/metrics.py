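"""Region-overlap localization metrics: IoU, IoR and IoD.

Given a rasterized reference ROI R (the expert-annotated nodule box) and a
detected region D (a detector's boxes or a thresholded attention map), the
three overlap ratios are, in percent:

* IoU = |R ∩ D| / |R ∪ D| x 100  (intersection over union)
* IoR = |R ∩ D| / |R|      x 100  (how much of the reference is covered)
* IoD = |R ∩ D| / |D|      x 100  (how much of the detection is relevant)

IoU is bounded above by both IoR and IoD, and whenever the intersection is
nonempty the three are tied together by the harmonic identity
``1/IoU = 1/IoR + 1/IoD - 1`` (ratios taken on the 0-1 scale). Both facts
are cheap internal consistency checks and are asserted on every computed
triple.

Dataset-level summaries are the unweighted per-image mean of each component
and, for the localization criterion, the fraction of correctly classified
images whose IoU meets a threshold (30% in the reference protocol),
reported separately for true positives (malignant, the positive class) and
true negatives (benign).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import BENIGN, MALIGNANT, ShapeMismatchError


@dataclass(frozen=True)
class OverlapTriple:
    """IoU / IoR / IoD in percent, with the underlying pixel counts."""

    iou: float
    ior: float
    iod: float
    area_r: int
    area_d: int
    area_i: int
    empty_detection: bool = False

    def check_consistency(self, tol: float = 1e-9) -> None:
        """Assert the ordering bound and (when applicable) the harmonic identity."""
        assert -tol <= self.iou <= min(self.ior, self.iod) + tol <= 100 + tol, self
        if self.area_i > 0:
            lhs = 1.0 / (self.iou / 100.0)
            rhs = 1.0 / (self.ior / 100.0) + 1.0 / (self.iod / 100.0) - 1.0
            assert abs(lhs - rhs) <= 1e-6 * max(1.0, abs(rhs)), self


def overlap(R: np.ndarray, D: np.ndarray) -> OverlapTriple:
    """Compute the IoU/IoR/IoD triple from two binary masks of one shape.

    R must be nonempty (a reference ROI always exists in this framework).
    An empty D yields the all-zero triple with ``empty_detection=True``.
    """
    R = np.asarray(R, dtype=bool)
    D = np.asarray(D, dtype=bool)
    if R.shape != D.shape:
        raise ShapeMismatchError(f"mask shapes differ: R {R.shape} vs D {D.shape}")
    area_r = int(R.sum())
    if area_r == 0:
        raise ValueError("reference mask R is empty")
    area_d = int(D.sum())
    if area_d == 0:
        return OverlapTriple(0.0, 0.0, 0.0, area_r, 0, 0, empty_detection=True)
    area_i = int((R & D).sum())
    area_u = area_r + area_d - area_i
    triple = OverlapTriple(
        iou=100.0 * area_i / area_u,
        ior=100.0 * area_i / area_r,
        iod=100.0 * area_i / area_d,
        area_r=area_r,
        area_d=area_d,
        area_i=area_i,
    )
    triple.check_consistency()
    return triple


def dataset_mean(triples: Sequence[OverlapTriple]) -> OverlapTriple:
    """Unweighted arithmetic mean of each component over a nonempty list.

    Every image counts equally regardless of its size. Values are exact;
    the report writers round to 2 decimals.
    """
    if not triples:
        raise ValueError("dataset_mean of an empty list")
    return OverlapTriple(
        iou=float(np.mean([t.iou for t in triples])),
        ior=float(np.mean([t.ior for t in triples])),
        iod=float(np.mean([t.iod for t in triples])),
        area_r=int(round(np.mean([t.area_r for t in triples]))),
        area_d=int(round(np.mean([t.area_d for t in triples]))),
        area_i=int(round(np.mean([t.area_i for t in triples]))),
        empty_detection=any(t.empty_detection for t in triples),
    )


@dataclass(frozen=True)
class LocalizedFractions:
    """Fraction of correctly classified images with IoU >= threshold, per class.

    A fraction is None (undefined) when its class has no correctly
    classified records, never 0.
    """

    threshold: float
    tp_fraction: Optional[float]
    tp_localized: int
    tp_total: int
    tn_fraction: Optional[float]
    tn_localized: int
    tn_total: int


def localized_fraction(
    records: Iterable[Tuple[OverlapTriple, str, str]], threshold: float = 30.0
) -> LocalizedFractions:
    """Localization success among true positives and true negatives.

    ``records`` are (triple, predicted label, gold label); malignant is the
    positive class. An IoU exactly at the threshold counts as localized.
    """
    if not (0 < threshold <= 100):
        raise ValueError(f"threshold must lie in (0, 100], got {threshold}")
    tp_total = tp_loc = tn_total = tn_loc = 0
    for triple, predicted, gold in records:
        if gold == MALIGNANT and predicted == MALIGNANT:
            tp_total += 1
            tp_loc += triple.iou >= threshold
        elif gold == BENIGN and predicted == BENIGN:
            tn_total += 1
            tn_loc += triple.iou >= threshold
    return LocalizedFractions(
        threshold=threshold,
        tp_fraction=(tp_loc / tp_total if tp_total else None),
        tp_localized=tp_loc,
        tp_total=tp_total,
        tn_fraction=(tn_loc / tn_total if tn_total else None),
        tn_localized=tn_loc,
        tn_total=tn_total,
    )
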