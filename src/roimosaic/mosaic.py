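"""Composite (mosaic) input construction with exact ROI bookkeeping.

Builds the fixed-layout 1x2 and 2x2 composite inputs used to train
detection models on mixed benign/malignant content: class-balancing
oversampling, tile-size harmonization, blitting at fixed grid cells, exact
transformation of every ROI box into composite coordinates, and rotational
arrangements of the four quadrants. Every transform applied to a tile is
recorded in a provenance record so that each composite box can be traced
back to its source image and original coordinates.

Grid cells are named 1-based as ``(row, col)``; the default 2x2 placement
puts benign tiles on the main diagonal, cells (1,1) and (2,2), and
malignant tiles on the anti-diagonal, cells (1,2) and (2,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .geometry import BENIGN, LABELS, MALIGNANT, AnnotatedImage, RoiBox

ONE_BY_TWO = "one_by_two"
TWO_BY_TWO = "two_by_two"

Cell = Tuple[int, int]

# ring order used by the quadrant-permutation "rotational arrangements"
_RING: Tuple[Cell, ...] = ((1, 1), (1, 2), (2, 2), (2, 1))


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


@dataclass(frozen=True)
class MosaicLayout:
    """Grid kind, harmonized tile size, and cell-to-class placement."""

    kind: str
    tile_w: int
    tile_h: int
    placement: Mapping[Cell, str]

    def __post_init__(self) -> None:
        if self.kind not in (ONE_BY_TWO, TWO_BY_TWO):
            raise ValueError(f"unknown layout kind {self.kind!r}")
        if self.tile_w < 8 or self.tile_h < 8:
            raise ValueError("tile dimensions must be >= 8 px")
        labels = sorted(self.placement.values())
        if self.kind == TWO_BY_TWO:
            expected_cells = {(1, 1), (1, 2), (2, 1), (2, 2)}
            if set(self.placement) != expected_cells or labels != [
                BENIGN,
                BENIGN,
                MALIGNANT,
                MALIGNANT,
            ]:
                raise ValueError("2x2 placement must map the four cells to 2 benign + 2 malignant")
        else:
            if set(self.placement) != {(1, 1), (1, 2)} or labels != [BENIGN, MALIGNANT]:
                raise ValueError("1x2 placement must map (1,1),(1,2) to one benign + one malignant")
        object.__setattr__(self, "placement", dict(self.placement))

    @classmethod
    def default_2x2(cls, tile_w: int = 128, tile_h: int = 128) -> "MosaicLayout":
        placement = {(1, 1): BENIGN, (2, 2): BENIGN, (1, 2): MALIGNANT, (2, 1): MALIGNANT}
        return cls(TWO_BY_TWO, tile_w, tile_h, placement)

    @classmethod
    def default_1x2(cls, tile_w: int = 128, tile_h: int = 128) -> "MosaicLayout":
        return cls(ONE_BY_TWO, tile_w, tile_h, {(1, 1): BENIGN, (1, 2): MALIGNANT})

    @property
    def grid(self) -> Tuple[int, int]:
        return (2, 2) if self.kind == TWO_BY_TWO else (1, 2)

    @property
    def cells(self) -> List[Cell]:
        rows, cols = self.grid
        return [(r, c) for r in range(1, rows + 1) for c in range(1, cols + 1)]

    def cell_offset(self, cell: Cell) -> Tuple[int, int]:
        """Pixel offset (dx, dy) of a cell's upper-left corner."""
        r, c = cell
        return ((c - 1) * self.tile_w, (r - 1) * self.tile_h)

    def cell_of_point(self, cx: float, cy: float) -> Cell:
        """Grid cell containing a point; boundary ties go to the lower-index cell."""
        rows, cols = self.grid
        col = 1 if (cols == 1 or cx <= self.tile_w) else 2
        row = 1 if (rows == 1 or cy <= self.tile_h) else 2
        return (row, col)

    def composite_shape(self) -> Tuple[int, int]:
        rows, cols = self.grid
        return (rows * self.tile_h, cols * self.tile_w)

    def with_placement(self, placement: Mapping[Cell, str]) -> "MosaicLayout":
        return MosaicLayout(self.kind, self.tile_w, self.tile_h, placement)


@dataclass(frozen=True)
class TileProvenance:
    """How one source image ended up in one grid cell.

    ``sx, sy`` are the harmonization scale factors, ``pad_left, pad_top`` the
    symmetric-padding offsets inside the tile, and ``tile_box`` the harmonized
    ROI in tile-local coordinates. Inverting pad + scale on ``tile_box``
    recovers ``source_box`` (within 1 px when scaling rounded).
    """

    image_id: str
    cell: Cell
    label: str
    sx: float
    sy: float
    pad_left: int
    pad_top: int
    source_box: RoiBox
    tile_box: RoiBox

    def recover_source_box(self) -> RoiBox:
        """Invert the recorded translation and scale."""
        x = _round_half_up((self.tile_box.x - self.pad_left) / self.sx)
        y = _round_half_up((self.tile_box.y - self.pad_top) / self.sy)
        w = max(1, _round_half_up(self.tile_box.w / self.sx))
        h = max(1, _round_half_up(self.tile_box.h / self.sy))
        return RoiBox(x=x, y=y, w=w, h=h, label=self.label)


@dataclass
class CompositeImage:
    """A mosaic composite: pixels, ROI boxes in composite coordinates, provenance."""

    composite_id: str
    pixels: np.ndarray
    rois: List[RoiBox]
    provenance: List[TileProvenance]
    layout: MosaicLayout

    def __post_init__(self) -> None:
        expected = self.layout.composite_shape()
        if self.pixels.shape != expected:
            raise ValueError(f"composite pixels {self.pixels.shape} != layout shape {expected}")
        n_cells = len(self.layout.cells)
        if len(self.rois) != n_cells or len(self.provenance) != n_cells:
            raise ValueError(f"composite must carry exactly {n_cells} boxes and provenance records")
        counts = {lab: 0 for lab in LABELS}
        for box in self.rois:
            counts[box.label] += 1  # type: ignore[index]
        if self.layout.kind == TWO_BY_TWO and (counts[BENIGN] != 2 or counts[MALIGNANT] != 2):
            raise ValueError(f"2x2 composite must carry 2 benign + 2 malignant boxes, got {counts}")
        for box, prov in zip(self.rois, self.provenance):
            dx, dy = self.layout.cell_offset(prov.cell)
            tile_extent = RoiBox(dx, dy, self.layout.tile_w, self.layout.tile_h)
            if not (
                box.x >= tile_extent.x
                and box.y >= tile_extent.y
                and box.x2 <= tile_extent.x2
                and box.y2 <= tile_extent.y2
            ):
                raise ValueError(f"composite ROI {box} escapes its tile at cell {prov.cell}")

    def as_annotated(self) -> AnnotatedImage:
        return AnnotatedImage(self.composite_id, self.pixels, list(self.rois))


@dataclass
class HarmonizedTile:
    """Result of fitting a source image into a fixed tile extent."""

    image: AnnotatedImage
    sx: float
    sy: float
    pad_left: int
    pad_top: int


def balance_classes(images: Sequence[AnnotatedImage], seed: int) -> List[AnnotatedImage]:
    """Equalize class counts by oversampling the smaller class with replacement.

    The larger class is untouched; the smaller class keeps its original
    members and is extended by seeded sampling with replacement, so the output
    is deterministic given the seed.
    """
    by_class: Dict[str, List[AnnotatedImage]] = {BENIGN: [], MALIGNANT: []}
    for img in images:
        if img.diagnosis not in LABELS:
            raise ValueError(f"image {img.image_id!r} has no benign/malignant diagnosis")
        by_class[img.diagnosis].append(img)
    for lab in LABELS:
        if not by_class[lab]:
            raise ValueError(f"cannot balance classes: no {lab} images supplied")
    n = max(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    out: List[AnnotatedImage] = list(images)
    for lab in LABELS:
        deficit = n - len(by_class[lab])
        if deficit > 0:
            idx = rng.integers(0, len(by_class[lab]), size=deficit)
            out.extend(by_class[lab][i] for i in idx)
    return out


def harmonize_tile(image: AnnotatedImage, tile_w: int, tile_h: int) -> HarmonizedTile:
    """Fit a source image into a (tile_w, tile_h) extent.

    The image is resized preserving aspect ratio to fit within the tile, then
    padded symmetrically with background value 0 to exactly tile size (the
    extra pixel of an odd remainder goes right/bottom). Every ROI box is
    scaled by the same factors (coordinates rounded half-up) and translated
    by the padding offsets.
    """
    if tile_w < 8 or tile_h < 8:
        raise ValueError("tile dimensions must be >= 8 px")
    rows, cols = image.shape
    s = min(tile_w / cols, tile_h / rows)
    new_w = max(1, _round_half_up(cols * s))
    new_h = max(1, _round_half_up(rows * s))
    new_w, new_h = min(new_w, tile_w), min(new_h, tile_h)
    sx, sy = new_w / cols, new_h / rows
    if (new_h, new_w) == (rows, cols):
        resized = image.pixels
    else:
        resized = _sk_resize(image.pixels, (new_h, new_w), order=1, anti_aliasing=s < 1, preserve_range=True)
        resized = np.clip(resized, 0.0, 1.0)
    pad_left = (tile_w - new_w) // 2
    pad_top = (tile_h - new_h) // 2
    tile = np.zeros((tile_h, tile_w), dtype=float)
    tile[pad_top : pad_top + new_h, pad_left : pad_left + new_w] = resized

    boxes: List[RoiBox] = []
    for box in image.rois:
        w = _round_half_up(box.w * sx)
        h = _round_half_up(box.h * sy)
        if w < 1 or h < 1:
            raise ValueError(
                f"ROI {box} of image {image.image_id!r} collapses to zero size at "
                f"tile ({tile_w}x{tile_h}); use a larger tile"
            )
        x = _round_half_up(box.x * sx) + pad_left
        y = _round_half_up(box.y * sy) + pad_top
        x = min(x, tile_w - w)
        y = min(y, tile_h - h)
        boxes.append(RoiBox(x=x, y=y, w=w, h=h, label=box.label))
    harmonized = AnnotatedImage(image.image_id, tile, boxes, image.diagnosis)
    return HarmonizedTile(harmonized, sx=sx, sy=sy, pad_left=pad_left, pad_top=pad_top)


def _build_composite(
    composite_id: str,
    assignment: Mapping[Cell, AnnotatedImage],
    layout: MosaicLayout,
) -> CompositeImage:
    pixels = np.zeros(layout.composite_shape(), dtype=float)
    rois: List[RoiBox] = []
    provenance: List[TileProvenance] = []
    for cell in layout.cells:
        source = assignment[cell]
        slot_label = layout.placement[cell]
        if len(source.rois) != 1:
            raise ValueError(
                f"source image {source.image_id!r} must carry exactly one ROI, has {len(source.rois)}"
            )
        src_box = source.rois[0]
        if src_box.label != slot_label:
            raise ValueError(
                f"cell {cell} expects a {slot_label} nodule but image "
                f"{source.image_id!r} is labeled {src_box.label}"
            )
        tile = harmonize_tile(source, layout.tile_w, layout.tile_h)
        dx, dy = layout.cell_offset(cell)
        pixels[dy : dy + layout.tile_h, dx : dx + layout.tile_w] = tile.image.pixels
        tile_box = tile.image.rois[0]
        # upper-left corner shifted by the cell offset; width/height preserved
        rois.append(tile_box.shifted(dx, dy))
        provenance.append(
            TileProvenance(
                image_id=source.image_id,
                cell=cell,
                label=slot_label,
                sx=tile.sx,
                sy=tile.sy,
                pad_left=tile.pad_left,
                pad_top=tile.pad_top,
                source_box=src_box,
                tile_box=tile_box,
            )
        )
    return CompositeImage(composite_id, pixels, rois, provenance, layout)


def build_2x2(
    benign_pair: Sequence[AnnotatedImage],
    malignant_pair: Sequence[AnnotatedImage],
    layout: Optional[MosaicLayout] = None,
    composite_id: str = "mosaic_2x2",
) -> CompositeImage:
    """Assemble two benign and two malignant single-nodule images into a 2x2 composite."""
    layout = layout or MosaicLayout.default_2x2()
    if layout.kind != TWO_BY_TWO:
        raise ValueError("build_2x2 requires a two_by_two layout")
    if len(benign_pair) != 2 or len(malignant_pair) != 2:
        raise ValueError("build_2x2 needs exactly two benign and two malignant images")
    pools = {BENIGN: list(benign_pair), MALIGNANT: list(malignant_pair)}
    assignment = {cell: pools[layout.placement[cell]].pop(0) for cell in layout.cells}
    return _build_composite(composite_id, assignment, layout)


def build_1x2(
    benign: AnnotatedImage,
    malignant: AnnotatedImage,
    layout: Optional[MosaicLayout] = None,
    composite_id: str = "mosaic_1x2",
) -> CompositeImage:
    """Concatenate one benign and one malignant image side-by-side."""
    layout = layout or MosaicLayout.default_1x2()
    if layout.kind != ONE_BY_TWO:
        raise ValueError("build_1x2 requires a one_by_two layout")
    pools = {BENIGN: [benign], MALIGNANT: [malignant]}
    assignment = {cell: pools[layout.placement[cell]].pop(0) for cell in layout.cells}
    return _build_composite(composite_id, assignment, layout)


def _permute_tiles(composite: CompositeImage, steps: int, suffix: str) -> CompositeImage:
    """Move each tile ``steps`` positions along the quadrant ring (clockwise)."""
    layout = composite.layout
    mapping = {_RING[i]: _RING[(i + steps) % 4] for i in range(4)}
    pixels = np.zeros_like(composite.pixels)
    rois: List[RoiBox] = []
    provenance: List[TileProvenance] = []
    new_placement: Dict[Cell, str] = {}
    for box, prov in zip(composite.rois, composite.provenance):
        old_dx, old_dy = layout.cell_offset(prov.cell)
        new_cell = mapping[prov.cell]
        new_dx, new_dy = layout.cell_offset(new_cell)
        pixels[new_dy : new_dy + layout.tile_h, new_dx : new_dx + layout.tile_w] = (
            composite.pixels[old_dy : old_dy + layout.tile_h, old_dx : old_dx + layout.tile_w]
        )
        rois.append(prov.tile_box.shifted(new_dx, new_dy))
        provenance.append(replace(prov, cell=new_cell))
        new_placement[new_cell] = prov.label
    new_layout = layout.with_placement(new_placement)
    return CompositeImage(composite.composite_id + suffix, pixels, rois, provenance, new_layout)


def _rotate_pixels(composite: CompositeImage, quarter_turns: int, suffix: str) -> CompositeImage:
    """Rotate the whole composite raster clockwise by 90-degree steps (2x2 only)."""
    layout = composite.layout
    size = layout.tile_w  # square tiles required for pixel rotation of a 2x2
    if layout.tile_w != layout.tile_h:
        raise ValueError("pixel-rotation mode requires square tiles")
    pixels = composite.pixels
    rois = list(composite.rois)
    cells = [p.cell for p in composite.provenance]
    for _ in range(quarter_turns):
        h_in = pixels.shape[0]
        pixels = np.rot90(pixels, k=-1)
        rois = [
            RoiBox(x=h_in - b.y - b.h, y=b.x, w=b.h, h=b.w, label=b.label) for b in rois
        ]
        cells = [(c, 3 - r) for (r, c) in cells]
    provenance = []
    new_placement: Dict[Cell, str] = {}
    for prov, cell, box in zip(composite.provenance, cells, rois):
        dx, dy = layout.cell_offset(cell)
        provenance.append(replace(prov, cell=cell, tile_box=box.shifted(-dx, -dy)))
        new_placement[cell] = prov.label
    new_layout = layout.with_placement(new_placement)
    return CompositeImage(composite.composite_id + suffix, pixels, rois, provenance, new_layout)


def rotational_arrangements(
    composite: CompositeImage, mode: str = "tiles"
) -> List[CompositeImage]:
    """The three 90/180/270-degree arrangements of a 2x2 composite.

    Default ``mode="tiles"`` permutes the four tiles cyclically around the
    grid, leaving pixels within each tile unrotated, so composite boxes move
    by pure translation and clinical orientation is untouched.
    ``mode="pixels"`` rotates the whole raster instead.
    """
    if composite.layout.kind != TWO_BY_TWO:
        raise ValueError("rotational arrangements are defined only for 2x2 composites")
    if mode == "tiles":
        return [_permute_tiles(composite, k, f"_rot{90 * k:03d}") for k in (1, 2, 3)]
    if mode == "pixels":
        return [_rotate_pixels(composite, k, f"_rot{90 * k:03d}") for k in (1, 2, 3)]
    raise ValueError(f"unknown rotation mode {mode!r}")


def annotation_frame(composites: Iterable[CompositeImage]) -> pd.DataFrame:
    """Flat annotation table, one row per composite box, in the standard dialect."""
    rows = []
    for comp in composites:
        for box in comp.rois:
            rows.append(
                {
                    "image_id": comp.composite_id,
                    "x": box.x,
                    "y": box.y,
                    "width": box.w,
                    "height": box.h,
                    "label": box.label,
                }
            )
    return pd.DataFrame(rows, columns=["image_id", "x", "y", "width", "height", "label"])


def build_dataset(
    sources: Sequence[AnnotatedImage],
    layout: Optional[MosaicLayout] = None,
    seed: int = 0,
    include_rotations: bool = True,
    rotation_mode: str = "tiles",
    balance: bool = True,
) -> Tuple[List[CompositeImage], pd.DataFrame]:
    """Build a full composite dataset from single-nodule sources.

    Sources are class-balanced by oversampling, shuffled deterministically,
    paired into composites, and (for 2x2) optionally expanded with the three
    rotational arrangements. Returns the composites and a flat annotation
    table with one row per composite box.
    """
    layout = layout or MosaicLayout.default_2x2()
    pool = balance_classes(sources, seed) if balance else list(sources)
    rng = np.random.default_rng(seed + 1)
    benign = [im for im in pool if im.diagnosis == BENIGN]
    malignant = [im for im in pool if im.diagnosis == MALIGNANT]
    rng.shuffle(benign)  # type: ignore[arg-type]
    rng.shuffle(malignant)  # type: ignore[arg-type]

    per_class = 2 if layout.kind == TWO_BY_TWO else 1
    n_comp = min(len(benign), len(malignant)) // per_class
    if n_comp == 0:
        raise ValueError(
            f"not enough images to form a {layout.kind} composite: "
            f"{len(benign)} benign, {len(malignant)} malignant (need {per_class} of each)"
        )
    composites: List[CompositeImage] = []
    for i in range(n_comp):
        b = benign[per_class * i : per_class * (i + 1)]
        m = malignant[per_class * i : per_class * (i + 1)]
        cid = f"mosaic_{i:04d}"
        if layout.kind == TWO_BY_TWO:
            comp = build_2x2(b, m, layout, composite_id=cid)
        else:
            comp = build_1x2(b[0], m[0], layout, composite_id=cid)
        composites.append(comp)
        if include_rotations and layout.kind == TWO_BY_TWO:
            composites.extend(rotational_arrangements(comp, mode=rotation_mode))
    return composites, annotation_frame(composites)
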