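"""Training and evaluation: target assignment, the composite detection loss
with a pluggable box-loss kind, decoding + NMS prediction, and a seeded SGD
loop with the study's schedule (3 warm-up epochs at momentum 0.8, then
momentum 0.937; fixed learning rate).

Box decoding follows the v6.0 convention: the center offset is
2*sigmoid(t)-0.5 relative to the cell, and width/height are
(2*sigmoid(t))^2 times the anchor, so decoded sizes stay within 4x the
anchor — matched by the assignment rule that discards ground-truth boxes
whose width or height ratio to the anchor exceeds ``anchor_t`` = 4. Each
ground truth is assigned at its center cell and the up-to-two neighbouring
cells its center is nearest to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from . import autodiff as ad
from .autodiff import Tensor
from .boxes import LossConfig, bbox_loss, pairwise_iou
from .metrics import MetricsReport, average_precision, nms
from .model import DetectionModel
from .synthetic import load_manifest, read_labels_yolo

__all__ = [
    "TrainConfig", "DetectionDataset", "assign_targets", "detection_loss",
    "predict", "train", "evaluate", "SGD", "OBJ_BALANCE",
]

# Per-head objectness balance weights by stride (4-head extends the 3-head
# convention downward).
OBJ_BALANCE = {4: 4.0, 8: 1.0, 16: 0.4, 32: 0.1}
OBJ_BALANCE_3HEAD = {8: 4.0, 16: 1.0, 32: 0.4}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters. Defaults follow the study schedule: 200
    epochs, 3 warm-up epochs at momentum 0.8, momentum 0.937 thereafter,
    learning rate 0.001, 640x640 input."""

    epochs: int = 200
    warmup_epochs: int = 3
    warmup_momentum: float = 0.8
    momentum: float = 0.937
    lr: float = 0.001
    img_size: int = 640
    batch_size: int = 8
    mosaic: bool = True
    loss: LossConfig = field(default_factory=lambda: LossConfig(kind="asiou"))
    seed: int = 0
    box_weight: float = 0.05
    obj_weight: float = 1.0
    anchor_t: float = 4.0
    conf_thr_eval: float = 0.001
    conf_thr: float = 0.25
    nms_iou: float = 0.45
    iou_aware_obj: float = 1.0
    iou_aware_obj_final: float | None = None  # linear ramp target over epochs
    ema: bool = False               # keep an EMA of weights; applied after training
    lr_schedule: str = "constant"   # or "cosine" (decays to lr_final_frac * lr)
    lr_final_frac: float = 0.1

    def __post_init__(self):
        if self.epochs <= 0 or self.lr <= 0:
            raise ValueError("epochs and lr must be positive")


class DetectionDataset:
    """Images + YOLO-txt labels from a dataset manifest part."""

    def __init__(self, manifest: dict | str | Path, part: str = "train",
                 img_size: int = 640):
        if not isinstance(manifest, dict):
            manifest = load_manifest(manifest)
        self.img_dir = Path(manifest[part])
        self.lbl_dir = Path(str(self.img_dir).replace("images", "labels"))
        self.paths = sorted(self.img_dir.glob("*.png")) + sorted(self.img_dir.glob("*.jpg"))
        self.img_size = img_size

    def __len__(self):
        return len(self.paths)

    def __getitem__(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Returns (image CHW float32 in [0,1], boxes (N, 4) normalized)."""
        p = self.paths[i]
        img = Image.open(p).convert("RGB")
        if img.size != (self.img_size, self.img_size):
            img = img.resize((self.img_size, self.img_size), Image.BILINEAR)
        arr = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
        lbl = self.lbl_dir / (p.stem + ".txt")
        boxes = (np.stack([b.to_array() for b in read_labels_yolo(lbl)])
                 if lbl.exists() and lbl.stat().st_size else np.zeros((0, 4)))
        return arr, boxes.astype(np.float64).reshape(-1, 4)


# -- target assignment ---------------------------------------------------------

def assign_targets(gt_per_image: list[np.ndarray], model: DetectionModel,
                   img_size: int, anchor_t: float = 4.0) -> list[dict]:
    """Assign ground-truth boxes to anchors and grid cells per head.

    For each head, a box is kept for an anchor when max(w-ratio, h-ratio,
    and their inverses) < ``anchor_t``; it is then placed at its center cell
    and the two adjacent cells nearest its center. Returns one dict per head
    with index arrays (img, anchor, gj, gi), target boxes in grid units, and
    the anchor sizes in grid units.
    """
    heads = []
    for stride in model.strides:
        n = img_size // stride
        anchors = np.array(model.detect.anchors[stride], dtype=np.float64) / stride
        na = len(anchors)
        bs, as_, gjs, gis, tboxes, anch = [], [], [], [], [], []
        for img_idx, gt in enumerate(gt_per_image):
            gt = np.asarray(gt, dtype=np.float64).reshape(-1, 4)
            if len(gt) == 0:
                continue
            inside = ((gt[:, 0] > 0) & (gt[:, 0] < 1) & (gt[:, 1] > 0) & (gt[:, 1] < 1))
            if not inside.all():
                warnings.warn("ground-truth box center outside image; rejected")
                gt = gt[inside]
            t = gt * n  # grid units
            for a_idx, (aw, ah) in enumerate(anchors):
                r = t[:, 2:4] / (aw, ah)
                keep = np.maximum(r, 1.0 / r).max(axis=1) < anchor_t
                for box in t[keep]:
                    cx, cy = box[0], box[1]
                    gi0, gj0 = int(cx), int(cy)
                    cells = [(gi0, gj0)]
                    fx, fy = cx - gi0, cy - gj0
                    if fx < 0.5 and gi0 > 0:
                        cells.append((gi0 - 1, gj0))
                    elif fx >= 0.5 and gi0 < n - 1:
                        cells.append((gi0 + 1, gj0))
                    if fy < 0.5 and gj0 > 0:
                        cells.append((gi0, gj0 - 1))
                    elif fy >= 0.5 and gj0 < n - 1:
                        cells.append((gi0, gj0 + 1))
                    for gi, gj in cells:
                        bs.append(img_idx)
                        as_.append(a_idx)
                        gjs.append(gj)
                        gis.append(gi)
                        tboxes.append(box)
                        anch.append((aw, ah))
        heads.append({
            "stride": stride, "n": n,
            "b": np.array(bs, int), "a": np.array(as_, int),
            "gj": np.array(gjs, int), "gi": np.array(gis, int),
            "tbox": (np.stack(tboxes) if tboxes else np.zeros((0, 4))),
            "anchors": (np.stack(anch) if anch else np.zeros((0, 2))),
        })
    return heads


def _bce_with_logits(x: Tensor, z: np.ndarray) -> Tensor:
    """Elementwise stable binary cross-entropy on logits."""
    return x.clamp(lo=0.0) - x * z + ((-1.0 * x.abs()).exp() + 1.0).log()


def detection_loss(preds: list[Tensor], gt_per_image: list[np.ndarray],
                   model: DetectionModel, cfg: TrainConfig):
    """Composite loss: box regression (configured IoU kind) + objectness BCE.

    The class term is omitted for single-class models. Objectness targets at
    assigned cells are the (detached) IoU of the decoded box with its target,
    clamped to [0, 1]; per-head losses carry the stride balance weights.
    Returns (total loss Tensor, components dict of floats).
    """
    heads = assign_targets(gt_per_image, model, cfg.img_size, cfg.anchor_t)
    balance = OBJ_BALANCE if len(model.strides) == 4 else OBJ_BALANCE_3HEAD
    na, no = model.detect.na, model.detect.no
    box_terms = []
    obj_terms = []
    n_assigned = 0
    iou_sum = 0.0
    for p, h in zip(preds, heads):
        B = p.shape[0]
        n = h["n"]
        p5 = p.reshape(B, na, no, n, n)
        tobj = np.zeros((B, na, n, n), dtype=np.float32)
        if len(h["b"]):
            n_assigned += len(h["b"])
            sel = p5.transpose(0, 1, 3, 4, 2)[h["b"], h["a"], h["gj"], h["gi"]]  # (nt, no)
            xy = sel[:, 0:2].sigmoid() * 2.0 - 0.5
            wh = (sel[:, 2:4].sigmoid() * 2.0) ** 2 * h["anchors"]
            cell = np.stack([h["gi"], h["gj"]], axis=1).astype(np.float64)
            pbox = ad.concat([xy + cell, wh], axis=1)
            li = bbox_loss(pbox, h["tbox"], cfg.loss)
            box_terms.append(li.mean())
            pb = pbox.data.astype(np.float64, copy=True)
            pb[:, 2:4] = np.maximum(pb[:, 2:4], 1e-9)  # sigmoid underflow guard
            iou_t = np.clip(np.diag(pairwise_iou(pb, h["tbox"])), 0.0, 1.0)
            iou_sum += float(iou_t.sum())
            gr = cfg.iou_aware_obj
            tobj[h["b"], h["a"], h["gj"], h["gi"]] = (
                (1.0 - gr) + gr * iou_t).astype(np.float32)
        obj_logits = p5[:, :, 4]
        lobj = _bce_with_logits(obj_logits, tobj).mean()
        obj_terms.append(lobj * balance[h["stride"]])
    box_loss = box_terms[0] if box_terms else Tensor(np.float32(0.0))
    for t in box_terms[1:]:
        box_loss = box_loss + t
    if box_terms:
        box_loss = box_loss * (1.0 / len(box_terms))
    obj_loss = obj_terms[0]
    for t in obj_terms[1:]:
        obj_loss = obj_loss + t
    total = cfg.box_weight * box_loss + cfg.obj_weight * obj_loss
    comps = {"box": float(np.asarray(box_loss.data)),
             "obj": float(np.asarray(obj_loss.data)),
             "total": float(np.asarray(total.data)),
             "n_assigned": n_assigned,
             "mean_iou": iou_sum / max(n_assigned, 1)}
    if not np.isfinite(comps["total"]):
        raise RuntimeError(f"non-finite detection loss: {comps}")
    return total, comps


# -- inference -----------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def predict(model: DetectionModel, images: np.ndarray,
            conf_thr: float = 0.25, nms_iou: float = 0.45,
            max_det: int = 300) -> list[tuple[np.ndarray, np.ndarray]]:
    """Run the detector and return per-image (boxes, scores) after NMS.

    ``images`` is (B, 3, H, W) float32 in [0, 1]; boxes come back in
    normalized center-size coordinates.
    """
    model.eval()
    img_size = images.shape[-1]
    with ad.no_grad():
        preds = model(Tensor(images))
    na, no = model.detect.na, model.detect.no
    results = []
    B = images.shape[0]
    all_boxes = [[] for _ in range(B)]
    all_scores = [[] for _ in range(B)]
    for p, stride in zip(preds, model.strides):
        n = img_size // stride
        raw = p.data.reshape(B, na, no, n, n)
        anchors = np.array(model.detect.anchors[stride]) / stride
        gx, gy = np.meshgrid(np.arange(n), np.arange(n))  # gx: (n,n) columns
        xy = _sigmoid(raw[:, :, 0:2]) * 2.0 - 0.5
        cx = (xy[:, :, 0] + gx[None, None]) * stride / img_size
        cy = (xy[:, :, 1] + gy[None, None]) * stride / img_size
        wh = np.maximum((_sigmoid(raw[:, :, 2:4]) * 2.0) ** 2, 1e-9)
        w = wh[:, :, 0] * anchors[None, :, 0, None, None] * stride / img_size
        h_ = wh[:, :, 1] * anchors[None, :, 1, None, None] * stride / img_size
        obj = _sigmoid(raw[:, :, 4])
        if no > 6:  # multi-class: objectness times best class probability
            cls = _sigmoid(raw[:, :, 5:]).max(axis=2)
            score = obj * cls
        else:       # single class: the class term is untrained, use objectness
            score = obj
        for b in range(B):
            m = score[b] >= conf_thr
            if not m.any():
                continue
            all_boxes[b].append(np.stack([cx[b][m], cy[b][m], w[b][m], h_[b][m]], axis=1))
            all_scores[b].append(score[b][m])
    for b in range(B):
        if not all_boxes[b]:
            results.append((np.zeros((0, 4)), np.zeros(0)))
            continue
        boxes = np.concatenate(all_boxes[b])
        scores = np.concatenate(all_scores[b])
        keep = nms(boxes, scores, iou_thr=nms_iou)[:max_det]
        results.append((boxes[keep], scores[keep]))
    return results


# -- optimisation --------------------------------------------------------------

class ModelEMA:
    """Exponential moving average of model weights, used for evaluation.

    Standard for this detector family: smooths the late-training weight
    trajectory. The decay warms up with the update count so early (random)
    weights wash out quickly.
    """

    def __init__(self, model: DetectionModel, decay: float = 0.999):
        self.params = model.parameters()
        self.shadow = [p.data.copy() for p in self.params]
        self.decay = decay
        self.updates = 0

    def update(self):
        self.updates += 1
        d = self.decay * (1 - np.exp(-self.updates / 200.0))
        for s, p in zip(self.shadow, self.params):
            s *= d
            s += (1.0 - d) * p.data

    def copy_to(self, model: DetectionModel):
        for s, p in zip(self.shadow, model.parameters()):
            p.data = s.copy()


class SGD:
    """Plain SGD with momentum."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.937):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data = p.data + v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _mosaic(ds: DetectionDataset, idxs, rng: np.random.Generator,
            img_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Stitch four samples into one (each scaled into a quadrant)."""
    half = img_size // 2
    canvas = np.zeros((3, img_size, img_size), dtype=np.float32)
    boxes_out = []
    offsets = [(0, 0), (0, half), (half, 0), (half, half)]
    for (oy, ox), j in zip(offsets, idxs):
        img, boxes = ds[j]
        small = np.stack([np.asarray(
            Image.fromarray((c * 255).astype(np.uint8)).resize((half, half),
                                                               Image.BILINEAR),
            dtype=np.float32) / 255.0 for c in img])
        canvas[:, oy:oy + half, ox:ox + half] = small
        if len(boxes):
            b = boxes.copy()
            b[:, 0] = b[:, 0] * 0.5 + ox / img_size
            b[:, 1] = b[:, 1] * 0.5 + oy / img_size
            b[:, 2:4] *= 0.5
            boxes_out.append(b)
    boxes = np.concatenate(boxes_out) if boxes_out else np.zeros((0, 4))
    boxes = boxes[(boxes[:, 2] * img_size >= 2) & (boxes[:, 3] * img_size >= 2)]
    return canvas, boxes


def train(model: DetectionModel, manifest: dict | str | Path,
          cfg: TrainConfig, log=None) -> dict:
    """Train in place; returns a history dict with per-epoch losses.

    SGD with the configured warm-up/momentum schedule; optional mosaic
    stitching of four samples. Fully seeded: the same seed reproduces the
    same epoch losses (single-threaded numerics).
    """
    train_ds = DetectionDataset(manifest, "train", cfg.img_size)
    val_ds = None
    man = manifest if isinstance(manifest, dict) else load_manifest(manifest)
    if "val" in man:
        val_ds = DetectionDataset(man, "val", cfg.img_size)
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), cfg.lr, cfg.momentum)
    ema = ModelEMA(model) if cfg.ema else None
    history = {"train_loss": [], "val_loss": [], "box": [], "obj": []}
    best = None
    for epoch in range(cfg.epochs):
        opt.momentum = (cfg.warmup_momentum if epoch < cfg.warmup_epochs
                        else cfg.momentum)
        if cfg.lr_schedule == "cosine":
            frac = cfg.lr_final_frac + (1 - cfg.lr_final_frac) * 0.5 * (
                1 + np.cos(np.pi * epoch / max(cfg.epochs - 1, 1)))
            opt.lr = cfg.lr * frac
        epoch_cfg = cfg
        if cfg.iou_aware_obj_final is not None:
            # anneal the objectness target from plain hits toward IoU scores
            t = epoch / max(cfg.epochs - 1, 1)
            gr = cfg.iou_aware_obj + (cfg.iou_aware_obj_final - cfg.iou_aware_obj) * t
            epoch_cfg = replace(cfg, iou_aware_obj_final=None, iou_aware_obj=gr)
        model.train()
        order = rng.permutation(len(train_ds))
        losses, boxes_l, objs_l = [], [], []
        for start in range(0, len(order), cfg.batch_size):
            idxs = order[start:start + cfg.batch_size]
            imgs, gts = [], []
            for j in idxs:
                if cfg.mosaic and rng.uniform() < 0.5:
                    quad = rng.integers(0, len(train_ds), size=3)
                    img, b = _mosaic(train_ds, [j, *quad], rng, cfg.img_size)
                else:
                    img, b = train_ds[j]
                imgs.append(img)
                gts.append(b)
            x = Tensor(np.stack(imgs), requires_grad=False)
            preds = model(x)
            loss, comps = detection_loss(preds, gts, model, epoch_cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                ema.update()
            losses.append(comps["total"])
            boxes_l.append(comps["box"])
            objs_l.append(comps["obj"])
        history["train_loss"].append(float(np.mean(losses)))
        history["box"].append(float(np.mean(boxes_l)))
        history["obj"].append(float(np.mean(objs_l)))
        if val_ds is not None and len(val_ds):
            model.eval()
            vlosses = []
            with ad.no_grad():
                for start in range(0, len(val_ds), cfg.batch_size):
                    imgs, gts = zip(*(val_ds[j] for j in
                                      range(start, min(start + cfg.batch_size, len(val_ds)))))
                    preds = model(Tensor(np.stack(imgs)))
                    _, comps = detection_loss(preds, list(gts), model, cfg)
                    vlosses.append(comps["total"])
            history["val_loss"].append(float(np.mean(vlosses)))
        if log is not None:
            log({"epoch": epoch, "train_loss": history["train_loss"][-1],
                 "val_loss": history["val_loss"][-1] if history["val_loss"] else None})
        if not np.isfinite(history["train_loss"][-1]):
            raise RuntimeError("training diverged (non-finite loss)")
        best = history["train_loss"][-1]
    if ema is not None:
        ema.copy_to(model)
    history["final_train_loss"] = best
    return history


def evaluate(model: DetectionModel, dataset: DetectionDataset,
             cfg: TrainConfig | None = None, batch_size: int = 8) -> MetricsReport:
    """Evaluate on a dataset split: predictions at a low confidence floor go
    through NMS, then ranked AP / precision / recall."""
    cfg = cfg or TrainConfig()
    dets, gts = [], []
    for start in range(0, len(dataset), batch_size):
        pairs = [dataset[j] for j in range(start, min(start + batch_size, len(dataset)))]
        imgs = np.stack([p[0] for p in pairs])
        res = predict(model, imgs, conf_thr=cfg.conf_thr_eval, nms_iou=cfg.nms_iou)
        dets.extend(res)
        gts.extend(p[1] for p in pairs)
    return average_precision(dets, gts, conf_thr=cfg.conf_thr)
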