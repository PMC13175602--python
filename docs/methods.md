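# Methods

## Coordinate and raster conventions

All boxes are 0-based, half-open, x = column, y = row, origin top-left: a
box `(x, y, w, h)` covers the pixel set `[x, x+w) × [y, y+h)`. This makes
rasterized areas exactly `w·h` and keeps rectangle arithmetic and pixel
counting in perfect agreement (a property the test suite checks against a
closed-form oracle). Annotations arriving in the 1-based corner-inclusive
dialect of MATLAB-era tooling are converted by
`convert_onebased_inclusive`, which maps `(x1,y1,x2,y2)` to
`(x1−1, y1−1, x2−x1+1, y2−y1+1)`. Grayscale intensities are normalized to
[0, 1] at load time so every metric is independent of file bit depth.

## Overlap metrics

For a reference ROI mask R and detected-region mask D, the package reports
IoU = |R∩D|/|R∪D|, IoR = |R∩D|/|R| and IoD = |R∩D|/|D|, each ×100. Two
exact identities are asserted on every computed triple as an internal
consistency check: the ordering bound 0 ≤ IoU ≤ min(IoR, IoD) ≤ 100 (since
|R∪D| ≥ max(|R|, |D|)) and, whenever the intersection is nonempty, the
harmonic identity 1/IoU = 1/IoR + 1/IoD − 1 on the 0–1 scale (substitute
|R∪D| = |R| + |D| − |R∩D|).

Conventions for degenerate inputs: an empty R is an error (a reference ROI
always exists in this framework); an empty D yields the all-zero triple
with an `empty_detection` flag rather than a NaN, since images without
detections still need a defined score. Dataset means are unweighted per
image regardless of image size; `dataset_mean` returns exact values and
the report writers round to 2 decimals, so a singleton mean is exactly its
input. The "localized" criterion counts, separately among true positives
(malignant classified malignant) and true negatives, the fraction with
IoU ≥ threshold (default 30%, with ≥ so a borderline case counts); a class
with no correctly classified records reports an undefined fraction (None),
never 0.

## Mosaic composites

The 2×2 layout places two benign nodules at cells (1,1) and (2,2) and two
malignant at (1,2) and (2,1) (1-based `(row, col)` naming); the 1×2 layout
concatenates one benign and one malignant tile side by side. Class balance
is restored before pairing by oversampling the smaller class with
replacement from a seeded generator; pairing into composites is a seeded
shuffle, as no canonical pairing scheme exists for this construction.

Clinical source images vary in size, so each tile is harmonized before
blitting: resized preserving aspect ratio to fit the tile, then padded
symmetrically with background value 0 (odd remainder to the right/bottom).
ROI coordinates are scaled by the same per-axis factors — rounded half-up
for cross-platform reproducibility — and translated by the padding offsets;
a ROI that would collapse below 1 px raises with a suggestion to enlarge
the tile. Placing a harmonized tile at its cell then only *translates* its
box by the cell offset, preserving width and height, so composite boxes
remain exact. Every tile carries a provenance record (source id, cell,
scale factors, padding); inverting pad + scale recovers the source box
within 1 px when scaling occurred and exactly otherwise — the round-trip
the acceptance checks assert.

"Rotational arrangements" of a 2×2 composite are implemented by default as
a cyclic permutation of the four tiles around the grid (ring
(1,1)→(1,2)→(2,2)→(2,1)), not as raster rotation: the intent of the
construction is to vary *where* each class appears, and rotating
ultrasound pixels would alter clinical orientation. The permutation has
order 4, so the three arrangements plus the original exhaust the cyclic
orbit with pairwise-distinct placements, each still carrying exactly 2
benign and 2 malignant boxes. A `mode="pixels"` variant that rotates the
whole raster (with exact box transformation) is provided for completeness.
Whether oversampling preceded or followed pairing in the original
experimental protocol is unknowable from the outside; this package
balances first, which keeps every composite's class bookkeeping trivially
valid.

## Top-k% regionization

A score map is reduced to a region by selecting the smallest threshold t
such that pixels with score ≥ t number at least k% of all pixels, then
including *every* pixel tied at t. Thresholding by pixel-count percentile
(rather than by fraction of the maximum score) was chosen because it fixes
the nominal mask area independently of the score distribution's scale; tie
inclusion makes the rule deterministic and order-independent at the cost
of `k_realized ≥ k`, which is reported alongside. Consequences worth
knowing: masks nest as k grows (so IoR is non-decreasing in k while IoD
decays), and a map with a large tied plateau — e.g. the rule-based
saliency map below, which clips to 0 over the background — can jump to
`k_realized = 100` once k reaches the plateau. A constant map cannot be
regionized and returns the full mask with a warning. Detector outputs are
regionized by rasterizing and unioning all boxes into one D per image (the
evaluation treats the detected area as a single region even when the
detector emits several boxes — an explicit choice, recorded here).

For composites scored per nodule, detections are assigned to grid cells by
box-center membership (boundary ties to the lower-index cell) and each
ground-truth box is scored against the union of its own cell's detections;
a per-composite mode scoring against the union of all detections is also
available.

## Classification evaluation

Malignant is the positive class. Rates are reported to 4 decimals; a rate
with a zero denominator is undefined, never 0. The two composite
aggregation rules: **anchor** takes the label of the highest-confidence
detection in cell (1,1), falling back (flagged) to the vote when that cell
is empty; **vote** is a confidence-weighted majority with exact ties going
to malignant — the sensitivity-favoring tie-break, mirroring the clinical
cost asymmetry of missing a malignancy. Simple-majority and any-malignant
alternatives would be easy variants but are not needed by the shipped
pipelines. Note that a mixed-class 2×2 composite has no single gold label,
so the end-to-end benchmark measures accuracy per nodule (best detection
in the nodule's cell vs. that nodule's label, abstentions counting
against the gold class) and exercises the aggregators separately,
asserting only that they return a label for every composite.

Epoch-window reporting uses the arithmetic mean and the *sample* (n−1)
standard deviation over an inclusive epoch range (default 31–40, the
convergence-stage window); a length-1 window reports std 0 with a flag.

## Synthetic phantoms

The generator emulates the essential structure of a clinical thyroid
ultrasound set — grayscale speckle texture, one hypoechoic nodule per
image, a tight ROI box, a benign/malignant label, and an imbalanced
train/test split — and nothing more. Background: Gaussian-smoothed
(σ = 1.2 px) unit-variance noise scaled by `speckle_strength` around a
mean of 0.5, a cheap stand-in for multiplicative speckle; no acoustic
physics (attenuation, shadowing, probe geometry) is modeled. Nodule: an
ellipse whose normalized radius is perturbed by `amp·sin(fθ + φ)`
(f ∈ 5–9), darkened multiplicatively by `contrast`; malignant nodules are
taller than wide with amp = 0.2 and a Gaussian-blurred margin, benign ones
wider than tall with amp = 0 and a sharp margin. The benign/malignant
shape caricature encodes standard sonographic risk features (aspect ≥ 1,
irregular margin) so that a shape-based classifier has signal; it is not a
clinical model, and passing tests on phantoms demonstrates that the
*measurement machinery* is exact, not that any detector would perform
comparably on hospital data. The malignant aspect range (1.55–1.95) is
chosen so the taller-than-wide property survives the worst-case
perturbation: the bounding box is ~2a(1+amp) wide and ≥ 2b(1−amp) tall, so
h/w ≥ 1 needs b/a ≥ (1+amp)/(1−amp) = 1.5 at amp = 0.2. The emitted ROI
is the tight bounding box of the *binary* support (pre-blur), which makes
ground-truth recovery exact by construction.

Defaults: 128×128 px images, major diameter 34–58 px, contrast 0.35,
speckle 0.35 — values giving nodules that are visible but noisy at the
granularity of a downsampled clinical frame. The `easy_params`
configuration (contrast 0.55, speckle 0.15) defines the benchmark
condition under which the end-to-end thresholds (mean IoU ≥ 70, accuracy
≥ 0.9) are asserted. The default split sends 10% of benign and 25% of
malignant images to the test split, echoing (qualitatively, at desk scale)
the malignant-skewed test composition typical of FNA-confirmed clinical
series; a single override fraction is honored exactly on the total via
largest-remainder allocation across classes.

## Reference detector

A deterministic stand-in for a trained detection network: Gaussian smooth
(σ = 2.5), threshold at the 8th percentile of smoothed intensities (well
below the median, exploiting hypoechogenicity), connected components,
drop components with area < 150 px or contrast < 0.12 below the median
(the latter rejects speckle-tail blobs on nodule-free images), one tight
box per survivor with confidence = contrast/median. Classification of a
region: malignant iff the support's aspect h/w ≥ 1 or its hole-filled
boundary compactness perimeter²/(4π·area) exceeds 2.0 (a shape exactly at
a cutoff is malignant); confidence is a logistic transform (scale 6) of
the margin to the cutoff. All thresholds sit in one `DetectorConfig`
block because the detector is a test harness whose tuning must be visible;
they were set once against the generator's default phantoms by inspecting
component statistics (true nodules: area ≥ ~650, contrast ≥ ~0.17;
speckle blobs: area ≤ ~120, contrast ≤ ~0.09). The detector assumes a
darker-than-background target on a roughly stationary texture; it will
happily fire on the zero-padding of harmonized tiles of unequal sizes, so
the shipped pipelines build composites from same-size phantoms.

The companion `attention_map` (smoothed darkness below the median, clipped
at 0) plays the role of a classification network's activation heatmap for
the top-k% regionization pipeline.

## Problem sizes and determinism

The shipped benchmark uses 48 phantoms → 48 composites (with rotations) →
192 scored nodules, and 1,000 random box pairs for the metric-equivalence
check — sizes at which every result is exact or tightly concentrated while
the whole suite runs in seconds. All randomness (phantom sampling,
oversampling, pairing, splits) flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds reproduce every output byte
for byte, and the CLI records seed and configuration in a manifest per
run.

## Known limitations

- Rectangular ROIs only; free-form ROI masks are represented by their
  boxes before rasterization.
- No mAP/PR-style detection scoring; evaluation is against a single
  reference ROI per nodule.
- The phantom generator and rule-based detector share the same shape
  vocabulary by design; phantom results say nothing about absolute
  performance on clinical images.
- Score maps are inputs (or rule-based stand-ins); no network gradients
  are computed.
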