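"""A deterministic rule-based nodule detector and per-region classifier.

This stands in for a trained detection network so that the full
detect -> overlap -> aggregate -> rates pipeline can be exercised end to
end at desk scale. It exploits the one property every input shares —
nodules are hypoechoic (darker than the surrounding speckle):

1. smooth with a Gaussian;
2. threshold at a configurable low percentile of the smoothed intensities
   (well below the image median);
3. connected components; drop components below a minimum area or minimum
   contrast against the image median;
4. one tight box per surviving component; confidence = component contrast
   normalized by the median intensity.

Per-region classification mirrors the sonographic caricature the phantom
generator draws: a region is called malignant iff its thresholded support
is taller than wide (aspect h/w >= 1) or its boundary is non-compact
(perimeter^2 / (4*pi*area) above a cutoff); a shape exactly at the cutoff
is malignant. Confidence is a logistic transform of the margin to the
cutoff.

All thresholds live in one config block so the harness's tuning is visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter
from skimage import measure

from .geometry import BENIGN, MALIGNANT, AnnotatedImage, RoiBox

ABSTAIN = "abstain"


@dataclass(frozen=True)
class DetectorConfig:
    """Every tunable of the reference detector, with its default.

    smooth_sigma : Gaussian smoothing before thresholding (px).
    threshold_percentile : percentile of smoothed intensities used as the
        darkness threshold; must stay below 50 (the median).
    min_area : smallest component kept (px).
    min_contrast : smallest (median - component mean) kept, on the [0,1]
        intensity scale; rejects speckle-tail blobs on nodule-free images.
    compactness_cutoff : perimeter^2/(4*pi*area) above which a region is
        called malignant regardless of aspect.
    aspect_cutoff : h/w at or above which a region is called malignant.
    logistic_scale : steepness of the confidence transform.
    """

    smooth_sigma: float = 2.5
    threshold_percentile: float = 8.0
    min_area: int = 150
    min_contrast: float = 0.12
    compactness_cutoff: float = 2.0
    aspect_cutoff: float = 1.0
    logistic_scale: float = 6.0

    def __post_init__(self) -> None:
        if not (0 < self.threshold_percentile < 50):
            raise ValueError("threshold_percentile must lie in (0, 50)")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")


@dataclass
class DetectionResult:
    """Labeled, confidence-scored boxes for one image."""

    image_id: str
    boxes: List[Tuple[RoiBox, float]]

    def __post_init__(self) -> None:
        for box, conf in self.boxes:
            if not (0.0 <= conf <= 1.0):
                raise ValueError(f"confidence {conf} outside [0, 1] for box {box}")

    @property
    def labels(self) -> List[str]:
        return [box.label for box, _ in self.boxes]


def _as_pixels(image) -> Tuple[str, np.ndarray]:
    if isinstance(image, AnnotatedImage):
        return image.image_id, image.pixels
    return "image", np.asarray(image, dtype=float)


def _dark_components(pixels: np.ndarray, config: DetectorConfig):
    """Smoothed darkness threshold -> labeled connected components."""
    smoothed = gaussian_filter(pixels, sigma=config.smooth_sigma)
    threshold = np.percentile(smoothed, config.threshold_percentile)
    binary = smoothed <= threshold
    labeled = measure.label(binary, connectivity=2)
    return smoothed, labeled


def detect(image, config: Optional[DetectorConfig] = None) -> DetectionResult:
    """Detect hypoechoic regions; emits a tight unlabeled box per region.

    An empty result is valid (e.g. nodule-free speckle at default settings).
    Boxes are sorted by descending confidence, ties broken by position, so
    identical inputs always give identical output order.
    """
    config = config or DetectorConfig()
    image_id, pixels = _as_pixels(image)
    smoothed, labeled = _dark_components(pixels, config)
    median = float(np.median(smoothed))
    found: List[Tuple[RoiBox, float]] = []
    for region in measure.regionprops(labeled, intensity_image=smoothed):
        if region.area < config.min_area:
            continue
        contrast = median - float(region.intensity_mean)
        if contrast < config.min_contrast:
            continue
        y1, x1, y2, x2 = region.bbox
        conf = min(1.0, max(0.0, contrast / median)) if median > 0 else 1.0
        found.append((RoiBox(x=x1, y=y1, w=x2 - x1, h=y2 - y1), conf))
    found.sort(key=lambda bc: (-bc[1], bc[0].y, bc[0].x))
    return DetectionResult(image_id, found)


def classify_region(
    image, box: RoiBox, config: Optional[DetectorConfig] = None
) -> Tuple[str, float]:
    """Benign/malignant call for the thresholded support inside one box.

    Malignant iff aspect (h/w of the support's bounding box) >= aspect_cutoff
    or compactness (perimeter^2 / (4*pi*area)) > compactness_cutoff; a shape
    exactly at a cutoff is malignant. Returns (label, confidence); an empty
    support abstains with confidence 0.
    """
    config = config or DetectorConfig()
    _, pixels = _as_pixels(image)
    box.check_within(pixels.shape)
    _, labeled = _dark_components(pixels, config)
    window = labeled[box.y : box.y2, box.x : box.x2]
    support = window > 0
    if not support.any():
        return ABSTAIN, 0.0
    # largest component inside the box
    sub = measure.label(support, connectivity=2)
    regions = measure.regionprops(sub)
    region = max(regions, key=lambda r: r.area)
    y1, x1, y2, x2 = region.bbox
    aspect = (y2 - y1) / (x2 - x1)
    # fill holes so interior speckle dropouts don't inflate the perimeter
    filled = binary_fill_holes(sub == region.label)
    perimeter = max(measure.perimeter(filled), 1.0)
    compactness = perimeter**2 / (4.0 * math.pi * filled.sum())
    margin = max(aspect - config.aspect_cutoff, compactness - config.compactness_cutoff)
    label = MALIGNANT if margin >= 0 else BENIGN
    confidence = 1.0 / (1.0 + math.exp(-config.logistic_scale * abs(margin)))
    return label, confidence


def detect_and_classify(image, config: Optional[DetectorConfig] = None) -> DetectionResult:
    """Run detection then attach a class label and confidence to every box.

    The emitted confidence is the per-region classification confidence;
    boxes whose support vanished (cannot happen for boxes the detector
    itself produced) are dropped.
    """
    config = config or DetectorConfig()
    image_id, pixels = _as_pixels(image)
    result = detect(image, config)
    labeled_boxes: List[Tuple[RoiBox, float]] = []
    for box, _det_conf in result.boxes:
        label, conf = classify_region(pixels, box, config)
        if label == ABSTAIN:
            continue
        labeled_boxes.append((box.with_label(label), conf))
    return DetectionResult(image_id, labeled_boxes)


def attention_map(image, config: Optional[DetectorConfig] = None) -> np.ndarray:
    """A rule-based saliency map: darkness below the median, clipped at 0.

    Serves as a score-map source for top-k% regionization experiments
    (the same role a class-activation heatmap plays for a trained network).
    """
    config = config or DetectorConfig()
    _, pixels = _as_pixels(image)
    smoothed = gaussian_filter(pixels, sigma=config.smooth_sigma)
    return np.clip(np.median(smoothed) - smoothed, 0.0, None)
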