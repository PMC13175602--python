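# roimosaic

Tools for studying how expert region-of-interest (ROI) supervision shapes
detection and classification in ultrasound nodule imaging.

When a classification network is trained on thyroid ultrasound images
without ROI annotations, it can be right for the wrong reasons: attention
maps often concentrate on regions far from the nodule a radiologist would
point to. Quantifying that — and building the composite training inputs
that let detection networks learn from ROI-annotated, class-balanced,
spatially diverse data — requires a surprising amount of exact
bookkeeping: box coordinate transforms, mask rasterization, percentile
thresholding with well-defined tie rules, and per-class summaries.
`roimosaic` packages that machinery for people evaluating localization
quality of medical-imaging classifiers and detectors:

- **Mosaic composite construction** — fixed-layout 1×2 and 2×2 composites
  that place benign and malignant nodules at fixed grid cells (benign on
  the diagonal by default), with class-balancing oversampling, tile-size
  harmonization, rotational arrangements of the four quadrants, and
  provenance records that make every composite box traceable back to its
  source image exactly.
- **Attention regionization** — reduce a non-negative score map (e.g. a
  Grad-CAM heatmap exported from a CNN) to a detected region by keeping
  its top-k% highest-scoring pixels (ties at the threshold included).
- **Overlap metrics** — IoU, IoR and IoD between the reference ROI *R*
  and the detected region *D*, in percent:

  IoU = |R∩D|/|R∪D|·100, IoR = |R∩D|/|R|·100, IoD = |R∩D|/|D|·100,

  with dataset means and the "localized" fraction (IoU ≥ 30%) among true
  positives and true negatives.
- **Classification evaluation** — accuracy/sensitivity/specificity from
  confusion counts (malignant positive), two region-to-image aggregation
  rules for composite inputs (the (1,1)-anchor-cell rule and
  confidence-weighted voting), and mean ± std reporting over an epoch
  window.
- **Synthetic phantoms + reference detector** — a seeded generator of
  speckle-textured images with one hypoechoic nodule each (benign: smooth,
  wide; malignant: tall, irregular, blurred margin) and a deterministic
  rule-based detector/classifier, so the whole pipeline runs end to end
  without any clinical data.

## Worked example

```python
import roimosaic as rm

params = rm.easy_params(n_benign=12, n_malignant=12, seed=1)
sources = rm.generate_images(params)
composites, _ = rm.build_dataset(
    sources, rm.MosaicLayout.default_2x2(), seed=2, include_rotations=True
)
report = rm.run_composite_benchmark(composites)
m = report.mean_triple
print(f"mean IoU={m.iou:.2f}  IoR={m.ior:.2f}  IoD={m.iod:.2f}")
print(f"accuracy={report.rates.accuracy}  sensitivity={report.rates.sensitivity}")
```

prints (exact output of `examples/04_end_to_end.py`):

```
mean IoU=83.40  IoR=98.65  IoD=84.61
accuracy=1.0  sensitivity=1.0
```

Each of the 96 ground-truth nodules was scored against the detections in
its own grid cell: the detector's boxes overlap the reference ROIs at a
mean IoU of 83%, and every nodule was classified correctly — as expected
on the deliberately easy phantom configuration (high contrast, low
speckle). The `examples/` directory has one short script per capability.

A `roimosaic` command-line tool mirrors the library for scripted runs:
`synth`, `mosaic`, `detect`, `eval-overlap`, `eval-classify`; every
subcommand writes a `*.manifest.json` recording its resolved
configuration and seed.

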