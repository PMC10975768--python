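"""Train the full detector briefly on easy synthetic scenes and evaluate.

A deliberately small run (30 images, a few epochs at 64 px) that exercises
the whole pipeline on a laptop CPU in about a minute: scene generation,
anchor fitting by IoU k-means, SGD training with the warm-up momentum
schedule, decoding + NMS, and COCO-style mAP. Expect modest numbers — the
point is the moving parts, not a converged detector (see the test suite's
parameter-recovery check for a longer schedule that reaches mAP@0.5 > 0.5).
"""

import tempfile
from pathlib import Path

import numpy as np

from kyolo import SceneSpec, build, fit_anchors, make_dataset
from kyolo.train import DetectionDataset, TrainConfig, evaluate, train

root = Path(tempfile.mkdtemp())
make_dataset(30, root, seed=5, spec=SceneSpec.easy(size=64))
print(f"dataset at {root} (21 train / 6 val / 3 test)")

train_ds = DetectionDataset(root / "manifest.yaml", "train", 64)
boxes = np.concatenate([train_ds[i][1] for i in range(len(train_ds))
                        if len(train_ds[i][1])])
anchors = fit_anchors(boxes, strides=[4, 8, 16, 32], img_size=64, seed=0)
print("fitted stride-4 anchors (px):",
      [f"{w:.0f}x{h:.0f}" for w, h in anchors[4]])

model = build("kyolo", seed=0, anchors=anchors, img_size=64)
cfg = TrainConfig(epochs=8, img_size=64, batch_size=4, lr=0.03, mosaic=False,
                  seed=0, box_weight=0.35, iou_aware_obj=0.5,
                  iou_aware_obj_final=1.0, ema=True, lr_schedule="cosine")
history = train(model, root / "manifest.yaml", cfg)
print(f"train loss: {history['train_loss'][0]:.3f} -> "
      f"{history['train_loss'][-1]:.3f} over {cfg.epochs} epochs")

report = evaluate(model, DetectionDataset(root / "manifest.yaml", "val", 64), cfg)
print(f"val mAP@0.5 = {report.map50:.3f}, mAP@0.5:0.95 = {report.map50_95:.3f}, "
      f"P = {report.precision:.2f}, R = {report.recall:.2f}")
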