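"""Compute IoU / IoR / IoD for a reference ROI against a detected region.

Rasterizes two overlapping boxes on a small grid and prints the triple with
its two built-in consistency facts: IoU <= min(IoR, IoD) and the harmonic
identity 1/IoU = 1/IoR + 1/IoD - 1 (ratios on the 0-1 scale).
"""

import roimosaic as rm

shape = (20, 20)
R = rm.box_to_mask(rm.RoiBox(0, 0, 10, 10), shape)     # reference ROI, 100 px
D = rm.box_to_mask(rm.RoiBox(5, 0, 10, 10), shape)     # detection, half-overlapping

t = rm.overlap(R, D)
print(f"areas: R={t.area_r}, D={t.area_d}, intersection={t.area_i}")
print(f"IoU={t.iou:.2f}%  IoR={t.ior:.2f}%  IoD={t.iod:.2f}%")
print(f"ordering: IoU <= min(IoR, IoD): {t.iou <= min(t.ior, t.iod)}")
lhs = 1 / (t.iou / 100)
rhs = 1 / (t.ior / 100) + 1 / (t.iod / 100) - 1
print(f"harmonic identity: 1/IoU = {lhs:.4f} vs 1/IoR + 1/IoD - 1 = {rhs:.4f}")
# IoR says how much of the expert ROI was covered; IoD how much of the
# detection was relevant; IoU penalizes both misses and spill-over.
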