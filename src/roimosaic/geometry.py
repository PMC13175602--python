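"""Shared coordinate conventions, box/mask types, and rasterization primitives.

Conventions used throughout the package:

* pixel coordinates are 0-based; ``x`` indexes columns, ``y`` indexes rows,
  origin at the top-left;
* a box with upper-left corner ``(x, y)`` and size ``(w, h)`` covers the
  half-open pixel set ``[x, x+w) x [y, y+h)``;
* grayscale intensities are floats in ``[0, 1]`` regardless of the bit depth
  of the file they came from;
* binary masks are boolean numpy arrays with the same shape as their source
  image.

A converter is provided for annotations expressed in the 1-based
corner-inclusive dialect common to MATLAB-era tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

BENIGN = "benign"
MALIGNANT = "malignant"
LABELS = (BENIGN, MALIGNANT)


class BoundaryError(ValueError):
    """A box extends beyond the pixel grid it is being placed on."""


class ShapeMismatchError(ValueError):
    """Two rasters that must share a shape do not."""


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned box with an optional benign/malignant label.

    Covers the half-open pixel set ``[x, x+w) x [y, y+h)``.
    """

    x: int
    y: int
    w: int
    h: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"RoiBox.{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.w < 1 or self.h < 1:
            raise ValueError(
                f"RoiBox width and height must be >= 1, got w={self.w}, h={self.h}"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"RoiBox label must be one of {LABELS} or None, got {self.label!r}"
            )

    @property
    def x2(self) -> int:
        """One past the rightmost covered column."""
        return self.x + self.w

    @property
    def y2(self) -> int:
        """One past the bottom covered row."""
        return self.y + self.h

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def center(self) -> Tuple[float, float]:
        """Box center as (cx, cy) in pixel coordinates."""
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def shifted(self, dx: int, dy: int) -> "RoiBox":
        """Translate by integer offsets, preserving size and label."""
        return replace(self, x=self.x + dx, y=self.y + dy)

    def with_label(self, label: Optional[str]) -> "RoiBox":
        return replace(self, label=label)

    def fits_within(self, shape: Tuple[int, int]) -> bool:
        rows, cols = shape
        return self.x >= 0 and self.y >= 0 and self.x2 <= cols and self.y2 <= rows

    def check_within(self, shape: Tuple[int, int]) -> None:
        """Raise :class:`BoundaryError` naming the offending edge(s)."""
        rows, cols = shape
        bad = []
        if self.x < 0:
            bad.append(f"left edge x={self.x} < 0")
        if self.y < 0:
            bad.append(f"top edge y={self.y} < 0")
        if self.x2 > cols:
            bad.append(f"right edge x+w={self.x2} > grid width {cols}")
        if self.y2 > rows:
            bad.append(f"bottom edge y+h={self.y2} > grid height {rows}")
        if bad:
            raise BoundaryError(f"box {self} exceeds grid {shape}: " + "; ".join(bad))


@dataclass
class AnnotatedImage:
    """A grayscale raster plus zero or more labeled ROI boxes.

    ``diagnosis`` is the image-level gold-standard label. For single-nodule
    source images the single ROI's label equals the diagnosis.
    """

    image_id: str
    pixels: np.ndarray
    rois: list = field(default_factory=list)
    diagnosis: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"AnnotatedImage pixels must be 2-D, got shape {self.pixels.shape}"
            )
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("AnnotatedImage intensities must lie in [0, 1]")
        for box in self.rois:
            box.check_within(self.shape)
        if self.diagnosis is not None and self.diagnosis not in LABELS:
            raise ValueError(f"diagnosis must be one of {LABELS}, got {self.diagnosis!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def box_to_mask(box: RoiBox, shape: Tuple[int, int]) -> np.ndarray:
    """Rasterize a box to a boolean mask of the given ``(rows, cols)`` shape.

    The mask has exactly ``w * h`` True pixels at the half-open extent of the
    box. Raises :class:`BoundaryError` if the box does not fit.
    """
    box.check_within(shape)
    mask = np.zeros(shape, dtype=bool)
    mask[box.y : box.y2, box.x : box.x2] = True
    return mask


def union_masks(
    masks: Sequence[np.ndarray], shape: Optional[Tuple[int, int]] = None
) -> np.ndarray:
    """Pixelwise logical OR of binary masks sharing one shape.

    An empty list is allowed only when ``shape`` is supplied, in which case an
    all-False mask of that shape is returned.
    """
    masks = list(masks)
    if not masks:
        if shape is None:
            raise ValueError("union of zero masks requires an explicit shape")
        return np.zeros(shape, dtype=bool)
    ref = masks[0].shape
    if shape is not None and tuple(shape) != ref:
        raise ShapeMismatchError(f"mask shape {ref} differs from requested shape {tuple(shape)}")
    out = np.zeros(ref, dtype=bool)
    for m in masks:
        if m.shape != ref:
            raise ShapeMismatchError(f"mask shapes differ: {ref} vs {m.shape}")
        out |= m.astype(bool)
    return out


def convert_onebased_inclusive(
    corners: Tuple[int, int, int, int], label: Optional[str] = None
) -> RoiBox:
    """Convert a 1-based corner-inclusive ``(x1, y1, x2, y2)`` tuple to a RoiBox.

    The result is 0-based half-open with ``w = x2 - x1 + 1`` and
    ``h = y2 - y1 + 1``. Inverted corners raise ``ValueError``.
    """
    x1, y1, x2, y2 = corners
    if min(x1, y1, x2, y2) < 1:
        raise ValueError(f"1-based corners must all be >= 1, got {corners}")
    if x2 < x1 or y2 < y1:
        raise ValueError(f"inverted corners in {corners}: require x1 <= x2 and y1 <= y2")
    return RoiBox(x=x1 - 1, y=y1 - 1, w=x2 - x1 + 1, h=y2 - y1 + 1, label=label)


def mask_tight_bbox(mask: np.ndarray, label: Optional[str] = None) -> RoiBox:
    """Tight bounding box of the True pixels of a mask.

    Raises ``ValueError`` on an empty mask.
    """
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("cannot take the bounding box of an empty mask")
    y, y2 = int(rows[0]), int(rows[-1]) + 1
    x, x2 = int(cols[0]), int(cols[-1]) + 1
    return RoiBox(x=x, y=y, w=x2 - x, h=y2 - y, label=label)


def validate_score_map(values: np.ndarray) -> np.ndarray:
    """Check a score map: 2-D, finite, non-negative. Returns a float array."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"score map must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("score map contains non-finite values")
    if arr.size and arr.min() < 0:
        raise ValueError("score map contains negative values")
    return arr
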