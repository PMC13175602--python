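"""End-to-end evaluation pipelines tying the modules together.

Two evaluation paths mirror the two kinds of detected region:

* detector boxes on composites or single images -> per-nodule IoU/IoR/IoD,
  per-nodule classification rates, localized fractions, and the two
  composite-level aggregation rules;
* attention score maps on single images -> top-k% regionization at a list
  of k values and the overlap of each mask with the reference ROI.

On composites, detections are assigned to grid cells by box-center
membership and each ground-truth box is scored against the union of its
own cell's detections (per-nodule mode); a composite-level mode scoring
each box against the union of all detections is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import (
    ABSTAIN,
    AggregationOutcome,
    ConfusionCounts,
    ClassificationRates,
    aggregate_anchor_cell,
    aggregate_vote,
    rates,
)
from .detector import DetectionResult, DetectorConfig, attention_map, detect_and_classify
from .geometry import BENIGN, MALIGNANT, AnnotatedImage, RoiBox, box_to_mask, union_masks
from .metrics import LocalizedFractions, OverlapTriple, dataset_mean, localized_fraction, overlap
from .mosaic import CompositeImage, MosaicLayout
from .regions import detections_to_mask, topk_mask


@dataclass
class NoduleRecord:
    """One ground-truth nodule scored against the detections of its cell."""

    image_id: str
    gt_box: RoiBox
    gold: str
    predicted: str  # benign | malignant | abstain
    confidence: float
    triple: OverlapTriple


def assign_to_cells(
    dets: DetectionResult, layout: MosaicLayout
) -> Dict[Tuple[int, int], List[Tuple[RoiBox, float]]]:
    """Group detections by the grid cell containing each box center."""
    cells: Dict[Tuple[int, int], List[Tuple[RoiBox, float]]] = {}
    for box, conf in dets.boxes:
        cells.setdefault(layout.cell_of_point(*box.center), []).append((box, conf))
    return cells


def evaluate_composite(
    composite: CompositeImage,
    dets: DetectionResult,
    mode: str = "per_nodule",
) -> List[NoduleRecord]:
    """Score every ground-truth box of a composite against the detections.

    ``per_nodule`` (default): D for each box is the union of the detections
    in that box's cell; the predicted label is the highest-confidence
    detection there (abstain when the cell is empty). ``per_composite``:
    D is the union of all detections.
    """
    if mode not in ("per_nodule", "per_composite"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    shape = composite.pixels.shape
    by_cell = assign_to_cells(dets, composite.layout)
    records = []
    for gt_box, prov in zip(composite.rois, composite.provenance):
        if mode == "per_nodule":
            cell_dets = by_cell.get(prov.cell, [])
        else:
            cell_dets = list(dets.boxes)
        d_mask = union_masks([box_to_mask(b, shape) for b, _ in cell_dets], shape=shape)
        triple = overlap(box_to_mask(gt_box, shape), d_mask)
        if cell_dets:
            best_box, best_conf = max(cell_dets, key=lambda bc: bc[1])
            predicted, confidence = best_box.label or ABSTAIN, best_conf
        else:
            predicted, confidence = ABSTAIN, 0.0
        records.append(
            NoduleRecord(
                image_id=composite.composite_id,
                gt_box=gt_box,
                gold=gt_box.label,  # type: ignore[arg-type]
                predicted=predicted,
                confidence=confidence,
                triple=triple,
            )
        )
    return records


def evaluate_single_image(image: AnnotatedImage, dets: DetectionResult) -> List[NoduleRecord]:
    """Score a single-nodule image: D is the union of all detections."""
    shape = image.shape
    d_mask = detections_to_mask(dets, shape)
    records = []
    for gt_box in image.rois:
        triple = overlap(box_to_mask(gt_box, shape), d_mask)
        if dets.boxes:
            best_box, best_conf = max(dets.boxes, key=lambda bc: bc[1])
            predicted, confidence = best_box.label or ABSTAIN, best_conf
        else:
            predicted, confidence = ABSTAIN, 0.0
        records.append(
            NoduleRecord(image.image_id, gt_box, gt_box.label, predicted, confidence, triple)
        )
    return records


def evaluate_annotated(
    image: AnnotatedImage,
    dets: DetectionResult,
    layout: Optional[MosaicLayout] = None,
    mode: str = "per_nodule",
) -> List[NoduleRecord]:
    """Score a disk-loaded annotated image (single or composite).

    With a layout and ``per_nodule`` mode, detections and ground-truth
    boxes are matched through the grid cell containing their centers;
    otherwise every box is scored against the union of all detections.
    """
    if layout is None or mode == "per_composite":
        return evaluate_single_image(image, dets)
    shape = image.shape
    by_cell = assign_to_cells(dets, layout)
    records = []
    for gt_box in image.rois:
        cell = layout.cell_of_point(*gt_box.center)
        cell_dets = by_cell.get(cell, [])
        d_mask = union_masks([box_to_mask(b, shape) for b, _ in cell_dets], shape=shape)
        triple = overlap(box_to_mask(gt_box, shape), d_mask)
        if cell_dets:
            best_box, best_conf = max(cell_dets, key=lambda bc: bc[1])
            predicted, confidence = best_box.label or ABSTAIN, best_conf
        else:
            predicted, confidence = ABSTAIN, 0.0
        records.append(
            NoduleRecord(image.image_id, gt_box, gt_box.label, predicted, confidence, triple)
        )
    return records


def confusion_from_records(records: Sequence[NoduleRecord]) -> ConfusionCounts:
    """Per-nodule confusion counts; an abstention counts against its gold class."""
    tp = fp = tn = fn = 0
    for r in records:
        if r.gold == MALIGNANT:
            tp += r.predicted == MALIGNANT
            fn += r.predicted != MALIGNANT
        else:
            tn += r.predicted == BENIGN
            fp += r.predicted != BENIGN
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def records_frame(records: Sequence[NoduleRecord]) -> pd.DataFrame:
    rows = [
        {
            "image_id": r.image_id,
            "x": r.gt_box.x, "y": r.gt_box.y,
            "width": r.gt_box.w, "height": r.gt_box.h,
            "gold": r.gold, "predicted": r.predicted, "confidence": round(r.confidence, 4),
            "iou": round(r.triple.iou, 2), "ior": round(r.triple.ior, 2),
            "iod": round(r.triple.iod, 2),
            "empty_detection": r.triple.empty_detection,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


@dataclass
class BenchmarkReport:
    """Everything the end-to-end phantom benchmark measures."""

    records: List[NoduleRecord]
    mean_triple: OverlapTriple
    confusion: ConfusionCounts
    rates: ClassificationRates
    localized: LocalizedFractions
    anchor_outcomes: List[AggregationOutcome]
    vote_outcomes: List[AggregationOutcome]
    n_composites: int


def run_composite_benchmark(
    composites: Sequence[CompositeImage],
    config: Optional[DetectorConfig] = None,
    iou_threshold: float = 30.0,
    mode: str = "per_nodule",
) -> BenchmarkReport:
    """Detect + classify on every composite, then summarize.

    Produces the per-nodule overlap means, per-nodule classification rates,
    localized fractions at the IoU threshold, and both aggregation outcomes
    for every composite.
    """
    config = config or DetectorConfig()
    all_records: List[NoduleRecord] = []
    anchor_outcomes: List[AggregationOutcome] = []
    vote_outcomes: List[AggregationOutcome] = []
    for comp in composites:
        dets = detect_and_classify(comp.pixels, config)
        dets.image_id = comp.composite_id
        all_records.extend(evaluate_composite(comp, dets, mode=mode))
        anchor_outcomes.append(aggregate_anchor_cell(dets, comp.layout))
        vote_outcomes.append(aggregate_vote(dets))
    confusion = confusion_from_records(all_records)
    return BenchmarkReport(
        records=all_records,
        mean_triple=dataset_mean([r.triple for r in all_records]),
        confusion=confusion,
        rates=rates(confusion),
        localized=localized_fraction(
            [(r.triple, r.predicted, r.gold) for r in all_records], iou_threshold
        ),
        anchor_outcomes=anchor_outcomes,
        vote_outcomes=vote_outcomes,
        n_composites=len(composites),
    )


def evaluate_score_maps(
    images: Sequence[AnnotatedImage],
    score_maps: Optional[Dict[str, np.ndarray]] = None,
    ks: Sequence[float] = (30.0, 50.0, 70.0),
    config: Optional[DetectorConfig] = None,
) -> Dict[float, OverlapTriple]:
    """Mean IoU/IoR/IoD of top-k% attention masks against reference ROIs.

    ``score_maps`` maps image id -> score grid; when omitted, the rule-based
    saliency map (darkness below the median) is computed for each image.
    Returns the mean triple per k.
    """
    config = config or DetectorConfig()
    out: Dict[float, OverlapTriple] = {}
    for k in ks:
        triples = []
        for image in images:
            scores = (
                score_maps[image.image_id] if score_maps is not None else attention_map(image, config)
            )
            result = topk_mask(scores, k)
            r_mask = union_masks(
                [box_to_mask(b, image.shape) for b in image.rois], shape=image.shape
            )
            triples.append(overlap(r_mask, result.mask))
        out[k] = dataset_mean(triples)
    return out
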