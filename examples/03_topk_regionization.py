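"""Threshold an attention score map at top 30/50/70% and score it against the ROI.

Uses the rule-based saliency map (darkness below the smoothed median) of a
synthetic phantom in place of a network's class-activation heatmap, then
shows the characteristic trade-off: as k grows the mask covers more of the
ROI (IoR rises) but dilutes into background (IoD falls).
"""

import roimosaic as rm

image = rm.generate_phantom(rm.easy_params(seed=7), "malignant")
scores = rm.attention_map(image)
R = rm.box_to_mask(image.rois[0], image.shape)

print(f"phantom ROI: {image.rois[0]}")
for k in (30, 50, 70):
    result = rm.topk_mask(scores, k)
    t = rm.overlap(R, result.mask)
    print(f"top {k:2d}%: realized {result.k_realized:5.1f}% of pixels, "
          f"IoU={t.iou:5.1f}  IoR={t.ior:5.1f}  IoD={t.iod:5.1f}")
# Larger k -> nested, larger masks: IoR is non-decreasing while IoD decays,
# which is why IoU (penalizing both) is the primary localization metric.
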