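"""Readers/writers for the package's on-disk dialects.

* grayscale PNG (8- or 16-bit), normalized to [0, 1] at load time;
* annotation CSV: header ``image_id,x,y,width,height,label``, one box per row;
* detection CSV: the same columns plus ``confidence``;
* score maps: a CSV numeric grid, or a 16-bit PNG with a sidecar scale factor.

Malformed CSV rows are reported with their line number (header = line 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import LABELS, AnnotatedImage, RoiBox
from .detector import DetectionResult

ANNOTATION_COLUMNS = ["image_id", "x", "y", "width", "height", "label"]
DETECTION_COLUMNS = ANNOTATION_COLUMNS + ["confidence"]


def load_image(path) -> np.ndarray:
    """Read a grayscale PNG as floats in [0, 1] (any integer bit depth)."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # tolerate grayscale saved with redundant channels
        arr = arr[..., 0]
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    return np.clip(arr.astype(float), 0.0, 1.0)


def save_image(path, pixels: np.ndarray, bitdepth: int = 8) -> None:
    """Write [0, 1] floats as an 8- or 16-bit grayscale PNG."""
    pixels = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    if bitdepth == 8:
        iio.imwrite(path, np.round(pixels * 255).astype(np.uint8))
    elif bitdepth == 16:
        iio.imwrite(path, np.round(pixels * 65535).astype(np.uint16))
    else:
        raise ValueError(f"bitdepth must be 8 or 16, got {bitdepth}")


def _check_columns(df: pd.DataFrame, expected: List[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected header {expected}")


def _parse_box(row, line_no: int, path, require_label: bool = True) -> RoiBox:
    try:
        label = row["label"] if pd.notna(row["label"]) else None
        if require_label and label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {label!r}")
        return RoiBox(
            x=int(row["x"]), y=int(row["y"]), w=int(row["width"]), h=int(row["height"]),
            label=label,
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}, line {line_no}: malformed box row ({exc})") from exc


def read_annotations(path) -> Dict[str, List[RoiBox]]:
    """Annotation CSV -> ordered boxes per image id."""
    df = pd.read_csv(path)
    _check_columns(df, ANNOTATION_COLUMNS, path)
    out: Dict[str, List[RoiBox]] = {}
    for i, row in df.iterrows():
        out.setdefault(str(row["image_id"]), []).append(_parse_box(row, i + 2, path))
    return out


def write_annotations(path, boxes_by_image: Dict[str, List[RoiBox]]) -> None:
    rows = [
        {"image_id": img, "x": b.x, "y": b.y, "width": b.w, "height": b.h, "label": b.label}
        for img, boxes in boxes_by_image.items()
        for b in boxes
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_detections(path) -> Dict[str, DetectionResult]:
    """Detection CSV -> DetectionResult per image id."""
    df = pd.read_csv(path)
    _check_columns(df, DETECTION_COLUMNS, path)
    grouped: Dict[str, List] = {}
    for i, row in df.iterrows():
        box = _parse_box(row, i + 2, path)
        try:
            conf = float(row["confidence"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {i + 2}: bad confidence {row['confidence']!r}") from exc
        if not (0.0 <= conf <= 1.0):
            raise ValueError(f"{path}, line {i + 2}: confidence {conf} outside [0, 1]")
        grouped.setdefault(str(row["image_id"]), []).append((box, conf))
    return {img: DetectionResult(img, boxes) for img, boxes in grouped.items()}


def write_detections(path, detections: Iterable[DetectionResult]) -> None:
    rows = [
        {
            "image_id": det.image_id,
            "x": b.x, "y": b.y, "width": b.w, "height": b.h,
            "label": b.label, "confidence": conf,
        }
        for det in detections
        for b, conf in det.boxes
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def load_score_map(path, scale: Optional[float] = None) -> np.ndarray:
    """Load a score map from a CSV grid or a 16-bit PNG.

    A PNG is stored as integers; ``scale`` (from the run config) converts
    counts back to scores as ``counts / scale`` and is required for PNGs.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    elif path.suffix.lower() == ".png":
        if scale is None:
            raise ValueError("a PNG score map needs its sidecar scale factor")
        arr = iio.imread(path).astype(float) / float(scale)
    else:
        raise ValueError(f"unsupported score-map format {path.suffix!r}")
    from .geometry import validate_score_map

    return validate_score_map(arr)


def save_score_map(path, values: np.ndarray, scale: float = 65535.0) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, values, delimiter=",", fmt="%.8g")
    elif path.suffix.lower() == ".png":
        counts = np.round(np.asarray(values, dtype=float) * scale)
        if counts.max(initial=0) > 65535:
            raise ValueError("score map overflows 16-bit PNG at this scale")
        iio.imwrite(path, counts.astype(np.uint16))
    else:
        raise ValueError(f"unsupported score-map format {path.suffix!r}")


def load_annotated_images(image_dir, annotations_path, manifest_path=None, split=None):
    """Assemble AnnotatedImages from a directory of PNGs + annotation CSV.

    With a manifest and a split name, only that split is loaded. Missing
    image files are reported by id.
    """
    image_dir = Path(image_dir)
    boxes_by_image = read_annotations(annotations_path)
    ids = list(boxes_by_image)
    diagnoses: Dict[str, Optional[str]] = {}
    if manifest_path is not None:
        manifest = pd.read_csv(manifest_path)
        if split is not None:
            keep = set(manifest.loc[manifest["split"] == split, "image_id"].astype(str))
            ids = [i for i in ids if i in keep]
        diagnoses = dict(zip(manifest["image_id"].astype(str), manifest["label"]))
    images = []
    missing = [i for i in ids if not (image_dir / f"{i}.png").exists()]
    if missing:
        raise FileNotFoundError(f"image file(s) missing from {image_dir}: {missing}")
    for image_id in ids:
        pixels = load_image(image_dir / f"{image_id}.png")
        rois = boxes_by_image[image_id]
        diagnosis = diagnoses.get(image_id)
        if diagnosis is None and len(rois) == 1:
            diagnosis = rois[0].label
        images.append(AnnotatedImage(image_id, pixels, rois, diagnosis))
    return images
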