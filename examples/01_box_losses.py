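"""Compare the IoU-loss family on one predicted/ground-truth box pair.

The pair below overlaps heavily but is offset along the diagonal — the
regime dense kelp strips create constantly. The alpha-S-IoU's cubic power
transform shrinks the loss near a perfect match and steepens it for poor
matches, which is exactly what sharpens gradients on overlapping targets.
"""

import numpy as np

from kyolo import LossConfig, alpha_siou_loss, bbox_loss, siou_loss
from kyolo.boxes import BoundingBox, LOSS_KINDS

pred = BoundingBox(cx=0.50, cy=0.50, w=0.20, h=0.20)
gt = BoundingBox(cx=0.60, cy=0.60, w=0.20, h=0.20)

print(f"pred {pred}\ngt   {gt}\n")
print("S-IoU decomposition (theta = 4, standard grouping):")
comp = siou_loss(pred, gt)
for name in ("iou", "angle", "distance", "shape", "total"):
    print(f"  {name:9s} {getattr(comp, name):.6f}")
# angle = 1.0: the centers are offset at exactly 45 degrees, the worst case
# for the angle cost; shape = 0: both boxes have identical width and height.

print("\nall loss kinds on the same pair:")
for kind in LOSS_KINDS:
    val = float(np.asarray(bbox_loss(pred.to_array(), gt.to_array(),
                                     LossConfig(kind=kind))))
    print(f"  {kind:6s} {val:.6f}")

print("\nalpha-S-IoU with alpha = 1 reproduces S-IoU exactly:")
a1 = alpha_siou_loss(pred, gt, LossConfig(kind="asiou", alpha=1.0))
print(f"  asiou(alpha=1) {a1.total:.12f}  vs  siou {comp.total:.12f}")
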