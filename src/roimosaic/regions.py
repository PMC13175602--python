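"""Turn score maps and detection outputs into binary detected-region masks.

An attention score map (e.g. a class-activation heatmap exported from a
classification network) is reduced to a detected region D by keeping its
top-k% highest-scoring pixels; detector outputs are reduced to D by
rasterizing and unioning their boxes. Both feed the overlap metrics.

"Top k%" is defined over pixel count: the smallest score threshold t such
that pixels with score >= t make up at least k% of the image is selected,
and every pixel tied at t is included. Tie inclusion can only enlarge the
mask, so the realized area fraction is reported alongside the request.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .geometry import box_to_mask, union_masks, validate_score_map


@dataclass
class RegionizationResult:
    """A top-k% mask plus the bookkeeping of how it was obtained."""

    mask: np.ndarray
    k_requested: float
    k_realized: float
    threshold_used: float
    constant_input: bool = False


def topk_mask(scores: np.ndarray, k: float) -> RegionizationResult:
    """Select the top-k% highest-scoring pixels of a score map.

    Parameters
    ----------
    scores : 2-D array of finite, non-negative values.
    k : percent in (0, 100].

    Notes
    -----
    All pixels tied at the selected threshold are included, so
    ``k_realized >= k``. A constant score map cannot be regionized; it is
    returned as a full mask with ``k_realized = 100`` and a warning.
    """
    if not (0 < k <= 100):
        raise ValueError(f"k must lie in (0, 100], got {k}")
    arr = validate_score_map(scores)
    n = arr.size
    if n == 0:
        raise ValueError("empty score map")
    flat = np.sort(arr, axis=None)[::-1]
    if flat[0] == flat[-1]:
        warnings.warn("constant score map: returning the full mask (k_realized = 100)")
        return RegionizationResult(
            mask=np.ones_like(arr, dtype=bool),
            k_requested=float(k),
            k_realized=100.0,
            threshold_used=float(flat[0]),
            constant_input=True,
        )
    n_target = max(1, math.ceil(k / 100.0 * n))
    t = float(flat[n_target - 1])
    mask = arr >= t
    return RegionizationResult(
        mask=mask,
        k_requested=float(k),
        k_realized=100.0 * float(mask.sum()) / n,
        threshold_used=t,
    )


def detections_to_mask(dets, shape: Tuple[int, int]) -> np.ndarray:
    """Union of the rasterized boxes of a detection result.

    An empty detection list yields an empty mask of the given shape.
    """
    return union_masks([box_to_mask(box, shape) for box, _conf in dets.boxes], shape=shape)
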