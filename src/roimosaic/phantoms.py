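"""Synthetic ultrasound nodule phantoms with known ROIs and labels.

Each phantom is a speckle-textured grayscale image carrying one hypoechoic
(darker-than-background) nodule, a tight bounding-box ROI around it, and a
benign/malignant diagnosis. The two classes are drawn as a deliberate
caricature of standard sonographic risk features, not as a clinical model:

* benign — smooth ellipse, wider than tall, sharp margin;
* malignant — taller than wide, sinusoidal radial boundary irregularity,
  Gaussian-blurred (ill-defined) margin.

The background is smoothed multiplicative speckle with mean intensity 0.5.
Everything is fully determined by the seed, and the emitted ROI is by
construction the exact tight bounding box of the rendered nodule support.

The malignant aspect-ratio range is tied to the irregularity amplitude: a
perturbed boundary reaches out to ``a*(1+amp)`` horizontally, so the
taller-than-wide invariant needs ``h/w >= (1+amp)/(1-amp)`` (1.5 at the
default amplitude 0.2); the default range 1.55-1.95 keeps a margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geometry import BENIGN, MALIGNANT, AnnotatedImage, RoiBox, mask_tight_bbox


@dataclass
class PhantomParams:
    """Knobs of the phantom generator.

    size_range is the nodule's major diameter in pixels (horizontal for
    benign, vertical for malignant). contrast is the fractional intensity
    drop of the nodule relative to the background, in [0, 1]. speckle_strength
    scales the multiplicative texture. irregularity_amplitude and
    margin_blur (pixels) apply to malignant nodules only.
    """

    image_w: int = 128
    image_h: int = 128
    n_benign: int = 10
    n_malignant: int = 10
    size_range: Tuple[float, float] = (34.0, 58.0)
    contrast: float = 0.35
    speckle_strength: float = 0.35
    irregularity_amplitude: float = 0.2
    margin_blur: float = 1.5
    benign_aspect_range: Tuple[float, float] = (0.50, 0.72)  # h/w
    malignant_aspect_range: Tuple[float, float] = (1.55, 1.95)  # h/w
    test_fraction_benign: float = 0.10
    test_fraction_malignant: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.contrast <= 1):
            raise ValueError("contrast must lie in [0, 1]")
        if self.speckle_strength < 0 or self.irregularity_amplitude < 0:
            raise ValueError("speckle strength and irregularity amplitude must be >= 0")
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("phantom counts must be >= 0")
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid size range {self.size_range}")
        if hi > min(self.image_w, self.image_h):
            raise ValueError(
                f"nodule size range {self.size_range} exceeds image extent "
                f"({self.image_w}x{self.image_h})"
            )


def easy_params(**overrides) -> PhantomParams:
    """A high-contrast, low-speckle configuration where localization is easy."""
    defaults = dict(contrast=0.55, speckle_strength=0.15)
    defaults.update(overrides)
    return PhantomParams(**defaults)


def _speckle_background(rng: np.random.Generator, shape, strength: float) -> np.ndarray:
    # smoothed multiplicative texture: mean ~0.5, granularity ~1.2 px
    noise = gaussian_filter(rng.standard_normal(shape), sigma=1.2)
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    return np.clip(0.5 * (1.0 + strength * noise), 0.0, 1.0)


def generate_phantom(
    params: PhantomParams,
    diagnosis: str,
    rng: Optional[np.random.Generator] = None,
    image_id: str = "phantom",
    return_support: bool = False,
):
    """Render one phantom of the requested diagnosis.

    Fully determined by the generator state (``rng`` or ``params.seed``).
    With ``return_support=True`` also returns the binary nodule support,
    whose tight bounding box is exactly the emitted ROI.
    """
    if diagnosis not in (BENIGN, MALIGNANT):
        raise ValueError(f"diagnosis must be benign or malignant, got {diagnosis!r}")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    h_img, w_img = params.image_h, params.image_w
    amp = params.irregularity_amplitude if diagnosis == MALIGNANT else 0.0

    major = rng.uniform(*params.size_range)
    if diagnosis == BENIGN:
        aspect = rng.uniform(*params.benign_aspect_range)  # h/w < 1
        a, b = major / 2.0, (major * aspect) / 2.0
    else:
        aspect = rng.uniform(*params.malignant_aspect_range)  # h/w > 1
        b, a = major / 2.0, (major / aspect) / 2.0
    freq = int(rng.integers(5, 10))
    phase = rng.uniform(0.0, 2.0 * np.pi)

    margin_x = a * (1.0 + amp) + params.margin_blur + 2.0
    margin_y = b * (1.0 + amp) + params.margin_blur + 2.0
    if 2 * margin_x >= w_img or 2 * margin_y >= h_img:
        raise ValueError(
            f"nodule (semi-axes {a:.1f}x{b:.1f}, amplitude {amp}) cannot fit in "
            f"a {w_img}x{h_img} image"
        )
    cx = rng.uniform(margin_x, w_img - margin_x)
    cy = rng.uniform(margin_y, h_img - margin_y)

    yy, xx = np.mgrid[0:h_img, 0:w_img]
    dx, dy = xx - cx, yy - cy
    rho = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    theta = np.arctan2(dy, dx)
    boundary = 1.0 + amp * np.sin(freq * theta + phase)
    support = rho <= boundary

    soft = support.astype(float)
    if diagnosis == MALIGNANT and params.margin_blur > 0:
        soft = gaussian_filter(soft, sigma=params.margin_blur)

    background = _speckle_background(rng, (h_img, w_img), params.speckle_strength)
    pixels = np.clip(background * (1.0 - params.contrast * soft), 0.0, 1.0)

    if params.contrast == 0:
        warnings.warn(f"contrast is 0: nodule of {image_id!r} is invisible; ROI emitted anyway")
    roi = mask_tight_bbox(support, label=diagnosis)
    image = AnnotatedImage(image_id, pixels, [roi], diagnosis)
    if return_support:
        return image, support
    return image


def generate_images(params: PhantomParams) -> List[AnnotatedImage]:
    """All phantoms of a dataset (benign first, then malignant), one rng stream."""
    rng = np.random.default_rng(params.seed)
    images = []
    for i in range(params.n_benign):
        images.append(generate_phantom(params, BENIGN, rng, image_id=f"phantom_b{i:04d}"))
    for i in range(params.n_malignant):
        images.append(generate_phantom(params, MALIGNANT, rng, image_id=f"phantom_m{i:04d}"))
    return images


def _allocate_test_counts(n_benign: int, n_malignant: int, fraction: float) -> Tuple[int, int]:
    """Split round(fraction * total) test slots across classes, largest remainder."""
    total = int(np.floor(fraction * (n_benign + n_malignant) + 0.5))
    quota_b = fraction * n_benign
    quota_m = fraction * n_malignant
    t_b, t_m = int(np.floor(quota_b)), int(np.floor(quota_m))
    remainders = sorted(
        [(quota_b - t_b, 0), (quota_m - t_m, 1)], key=lambda r: (-r[0], r[1])
    )
    for rem, cls in remainders:
        if t_b + t_m >= total:
            break
        if cls == 0 and t_b < n_benign:
            t_b += 1
        elif cls == 1 and t_m < n_malignant:
            t_m += 1
    return min(t_b, n_benign), min(t_m, n_malignant)


def split_manifest(
    images: List[AnnotatedImage],
    params: PhantomParams,
    test_fraction: Optional[float] = None,
) -> pd.DataFrame:
    """Assign each image to train/test.

    With ``test_fraction=None`` the per-class default fractions apply
    (rounded half-up per class); a single override fraction is honored on
    the total count exactly, allocated across classes by largest remainder.
    Assignment within a class is a seeded permutation.
    """
    rng = np.random.default_rng(params.seed + 10_000)
    benign = [im for im in images if im.diagnosis == BENIGN]
    malignant = [im for im in images if im.diagnosis == MALIGNANT]
    if test_fraction is None:
        t_b = int(np.floor(params.test_fraction_benign * len(benign) + 0.5))
        t_m = int(np.floor(params.test_fraction_malignant * len(malignant) + 0.5))
    else:
        if not (0 <= test_fraction < 1):
            raise ValueError("test_fraction must lie in [0, 1)")
        t_b, t_m = _allocate_test_counts(len(benign), len(malignant), test_fraction)
    rows = []
    for group, n_test in ((benign, t_b), (malignant, t_m)):
        order = rng.permutation(len(group))
        test_idx = set(order[:n_test].tolist())
        for i, im in enumerate(group):
            rows.append(
                {
                    "image_id": im.image_id,
                    "label": im.diagnosis,
                    "split": "test" if i in test_idx else "train",
                }
            )
    return pd.DataFrame(rows, columns=["image_id", "label", "split"])


def generate_dataset(
    params: PhantomParams,
    outdir: Optional[Path] = None,
    test_fraction: Optional[float] = None,
    overwrite: bool = False,
):
    """Generate a phantom dataset: images, annotation table, split manifest.

    With ``outdir`` set, writes one PNG per image plus ``annotations.csv``
    and ``manifest.csv``; refuses to clobber existing files unless
    ``overwrite`` is given.
    """
    if params.n_benign == 0 or params.n_malignant == 0:
        raise ValueError("generate_dataset needs at least one image per class")
    images = generate_images(params)
    annotations = pd.DataFrame(
        [
            {
                "image_id": im.image_id,
                "x": im.rois[0].x,
                "y": im.rois[0].y,
                "width": im.rois[0].w,
                "height": im.rois[0].h,
                "label": im.rois[0].label,
            }
            for im in images
        ],
        columns=["image_id", "x", "y", "width", "height", "label"],
    )
    manifest = split_manifest(images, params, test_fraction)
    if outdir is not None:
        from . import io as _io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        targets = [outdir / f"{im.image_id}.png" for im in images]
        targets += [outdir / "annotations.csv", outdir / "manifest.csv"]
        clashes = [p for p in targets if p.exists()]
        if clashes and not overwrite:
            raise FileExistsError(
                f"{len(clashes)} output file(s) already exist (e.g. {clashes[0]}); "
                "pass overwrite to replace them"
            )
        for im in images:
            _io.save_image(outdir / f"{im.image_id}.png", im.pixels)
        annotations.to_csv(outdir / "annotations.csv", index=False)
        manifest.to_csv(outdir / "manifest.csv", index=False)
    return images, annotations, manifest
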