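"""Model assembly: the YOLOv5-n baseline and its four ablation variants.

The five named variants mirror the study's ablation ladder:

========  =======  ======  ======  =========
variant   4-head   I-CBAM  GSConv  box loss
========  =======  ======  ======  =========
baseline  no       no      no      giou
model1    yes      no      no      giou
model2    yes      yes     no      giou
model3    yes      yes     yes     giou
kyolo     yes      yes     yes     asiou
========  =======  ======  ======  =========

The baseline is the v6.0 P5 layout (CBS/C3/SPPF backbone, FPN+PAN neck,
heads at strides 8/16/32). The 4-head variant inserts a CBS after the second
neck C3, upsamples, concatenates with the first backbone C3 output and adds
a stride-4 head (a 160x160 grid at 640x640 input). The inserted CBS uses a
3x3 kernel, the CBS default; this choice also reproduces the ~22% GFLOP
increase of the 4-head step, which a 1x1 lateral would not. I-CBAM blocks
sit immediately before each of the four head convolutions; GSConv replaces
the convolution inside every neck CBS. The loss kind changes no
architecture.

Models are described by an editable config dict (YAML-serialisable, one
``[from, repeats, kind, args]`` row per layer, as is conventional for this
model family) and scaled by width/depth multiples (0.25/0.33 for the n
size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .boxes import LOSS_KINDS, pairwise_iou

__all__ = [
    "ModelVariant", "VARIANTS", "ConfigurationError", "FlopReport",
    "DetectionModel", "Detect", "build", "count_flops", "fit_anchors",
    "variant_config", "load_config", "save_config", "DEFAULT_ANCHORS",
    "save_checkpoint", "load_checkpoint",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent model-variant configurations."""


@dataclass(frozen=True)
class ModelVariant:
    """Declarative switchboard for the four modifications."""

    name: str = "custom"
    four_head: bool = False
    icbam: bool = False
    gsconv_neck: bool = False
    loss_kind: str = "giou"
    num_classes: int = 1
    width_multiple: float = 0.25
    depth_multiple: float = 0.33

    def __post_init__(self):
        if self.loss_kind not in LOSS_KINDS:
            raise ConfigurationError(f"unknown loss kind {self.loss_kind!r}")
        if self.icbam and not self.four_head:
            raise ConfigurationError(
                "I-CBAM placement is defined only for the 4-head layout")
        if self.num_classes < 1:
            raise ConfigurationError("num_classes must be >= 1")


VARIANTS: dict[str, ModelVariant] = {
    "baseline": ModelVariant(name="baseline"),
    "model1": ModelVariant(name="model1", four_head=True),
    "model2": ModelVariant(name="model2", four_head=True, icbam=True),
    "model3": ModelVariant(name="model3", four_head=True, icbam=True, gsconv_neck=True),
    "kyolo": ModelVariant(name="kyolo", four_head=True, icbam=True, gsconv_neck=True,
                          loss_kind="asiou"),
}
VARIANTS["model4"] = VARIANTS["kyolo"]

# Default anchors (w, h) in pixels at 640 input, smallest stride first.
DEFAULT_ANCHORS = {
    4: [(5, 6), (8, 14), (15, 11)],
    8: [(10, 13), (16, 30), (33, 23)],
    16: [(30, 61), (62, 45), (59, 119)],
    32: [(116, 90), (156, 198), (373, 326)],
}


def _make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(math.ceil(x / divisor) * divisor))


# -- config templates ----------------------------------------------------------
# Rows are [from, repeats, kind, args]; channels in args are at full (x1.0)
# width and get scaled by width_multiple. 'from' of -1 means previous layer.
# "NeckConv" marks the neck CBS blocks that GSConv may replace.

_BACKBONE = [
    [-1, 1, "Conv", [64, 6, 2]],      # 0  P1/2
    [-1, 1, "Conv", [128, 3, 2]],     # 1  P2/4
    [-1, 3, "C3", [128]],             # 2
    [-1, 1, "Conv", [256, 3, 2]],     # 3  P3/8
    [-1, 6, "C3", [256]],             # 4
    [-1, 1, "Conv", [512, 3, 2]],     # 5  P4/16
    [-1, 9, "C3", [512]],             # 6
    [-1, 1, "Conv", [1024, 3, 2]],    # 7  P5/32
    [-1, 3, "C3", [1024]],            # 8
    [-1, 1, "SPPF", [1024, 5]],       # 9
]

_HEAD_3 = [
    [-1, 1, "NeckConv", [512, 1, 1]],         # 10
    [-1, 1, "Upsample", []],                  # 11
    [[-1, 6], 1, "Concat", []],               # 12
    [-1, 3, "C3", [512, False]],              # 13
    [-1, 1, "NeckConv", [256, 1, 1]],         # 14
    [-1, 1, "Upsample", []],                  # 15
    [[-1, 4], 1, "Concat", []],               # 16
    [-1, 3, "C3", [256, False]],              # 17  P3/8 out
    [-1, 1, "NeckConv", [256, 3, 2]],         # 18
    [[-1, 14], 1, "Concat", []],              # 19
    [-1, 3, "C3", [512, False]],              # 20  P4/16 out
    [-1, 1, "NeckConv", [512, 3, 2]],         # 21
    [[-1, 10], 1, "Concat", []],              # 22
    [-1, 3, "C3", [1024, False]],             # 23  P5/32 out
    [[17, 20, 23], 1, "Detect", [[8, 16, 32]]],
]

# 4-head neck: CBS (3x3) after the second neck C3, upsample, concat with the
# first backbone C3 output, C3, stride-4 head; then the symmetric PAN
# down-path re-joins the three upper levels.
_HEAD_4 = [
    [-1, 1, "NeckConv", [512, 1, 1]],         # 10
    [-1, 1, "Upsample", []],                  # 11
    [[-1, 6], 1, "Concat", []],               # 12
    [-1, 3, "C3", [512, False]],              # 13
    [-1, 1, "NeckConv", [256, 1, 1]],         # 14
    [-1, 1, "Upsample", []],                  # 15
    [[-1, 4], 1, "Concat", []],               # 16
    [-1, 3, "C3", [256, False]],              # 17  second neck C3
    [-1, 1, "NeckConv", [128, 3, 1]],         # 18  inserted CBS
    [-1, 1, "Upsample", []],                  # 19
    [[-1, 2], 1, "Concat", []],               # 20  join first backbone C3
    [-1, 1, "C3", [128, False]],              # 21  P2/4 out (160x160 at 640)
    [-1, 1, "NeckConv", [128, 3, 2]],         # 22
    [[-1, 18], 1, "Concat", []],              # 23
    [-1, 3, "C3", [256, False]],              # 24  P3/8 out
    [-1, 1, "NeckConv", [256, 3, 2]],         # 25
    [[-1, 14], 1, "Concat", []],              # 26
    [-1, 3, "C3", [512, False]],              # 27  P4/16 out
    [-1, 1, "NeckConv", [512, 3, 2]],         # 28
    [[-1, 10], 1, "Concat", []],              # 29
    [-1, 3, "C3", [1024, False]],             # 30  P5/32 out
    [[21, 24, 27, 30], 1, "Detect", [[4, 8, 16, 32]]],
]


def variant_config(variant: ModelVariant) -> dict:
    """Editable config dict for a variant (YAML-serialisable)."""
    head = [list(row) for row in (_HEAD_4 if variant.four_head else _HEAD_3)]
    if variant.icbam:
        # insert one I-CBAM immediately before each head convolution
        srcs, _, _, dargs = head[-1]
        base = len(_BACKBONE)
        new_srcs = []
        for s in srcs:
            head.insert(-1, [s, 1, "ICBAM", []])
            new_srcs.append(base + len(head) - 2)
        head[-1] = [new_srcs, 1, "Detect", dargs]
    neck_kind = "GSConv" if variant.gsconv_neck else "Conv"
    for row in head:
        if row[2] == "NeckConv":
            row[2] = neck_kind
    return {
        "name": variant.name,
        "num_classes": variant.num_classes,
        "width_multiple": variant.width_multiple,
        "depth_multiple": variant.depth_multiple,
        "loss_kind": variant.loss_kind,
        "backbone": [list(r) for r in _BACKBONE],
        "head": head,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# -- modules -------------------------------------------------------------------

class Detect(nn.Module):
    """Per-level 1x1 prediction convolutions.

    Each level emits (batch, anchors*(5+num_classes), H, W) raw maps in
    (x, y, w, h, objectness, classes...) order per anchor. Objectness biases
    are initialised to the usual low prior so early training is stable.
    """

    def __init__(self, channels: list[int], strides: list[int], num_classes: int = 1,
                 anchors: dict[int, list[tuple[float, float]]] | None = None,
                 img_size: int = 640):
        self.strides = list(strides)
        self.num_classes = num_classes
        self.na = 3
        self.no = 5 + num_classes
        anchors = anchors or DEFAULT_ANCHORS
        self.anchors = {s: [tuple(map(float, a)) for a in anchors[s]] for s in strides}
        self.m = nn.ModuleList(
            nn.Conv2d(c, self.na * self.no, 1, 1, 0, bias=True) for c in channels)
        for conv, s in zip(self.m, strides):
            b = conv.bias.data.reshape(self.na, self.no).copy()
            b[:, 4] += math.log(8.0 / (img_size / s) ** 2)   # obj: ~8 objects/img
            if num_classes > 1:
                b[:, 5:] += math.log(0.6 / (num_classes - 0.99))
            conv.bias.data = b.reshape(-1).copy()

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        return [conv(f) for conv, f in zip(self.m, feats)]


class DetectionModel(nn.Module):
    """A detector assembled from a config dict (see :func:`variant_config`)."""

    def __init__(self, cfg: dict, anchors=None, img_size: int = 640):
        self.cfg = cfg
        self.num_classes = cfg["num_classes"]
        wm, dm = cfg["width_multiple"], cfg["depth_multiple"]
        rows = [list(r) for r in cfg["backbone"]] + [list(r) for r in cfg["head"]]
        ch: list[int] = [3]
        layers = []
        self.save: set[int] = set()
        for i, (frm, n, kind, args) in enumerate(rows):
            n_s = max(round(n * dm), 1) if n > 1 else n
            srcs = [frm] if isinstance(frm, int) else list(frm)
            srcs = [s if s >= 0 else i + s for s in srcs]
            c1 = ch[srcs[0] + 1]
            if kind == "Conv":
                c2 = _make_divisible(args[0] * wm)
                m = nn.ConvBNAct(c1, c2, args[1], args[2])
            elif kind == "GSConv":
                c2 = _make_divisible(args[0] * wm)
                m = nn.GSConv(c1, c2, args[1], args[2])
            elif kind == "GhostConv":
                c2 = _make_divisible(args[0] * wm)
                m = nn.GhostConv(c1, c2, args[1], args[2])
            elif kind == "C3":
                c2 = _make_divisible(args[0] * wm)
                shortcut = args[1] if len(args) > 1 else True
                m = nn.C3(c1, c2, n_s, shortcut)
            elif kind == "SPPF":
                c2 = _make_divisible(args[0] * wm)
                m = nn.SPPF(c1, c2, args[1])
            elif kind == "Upsample":
                c2 = c1
                m = nn.Upsample2x()
            elif kind == "Concat":
                c2 = sum(ch[s + 1] for s in srcs)
                m = None
            elif kind == "ICBAM":
                c2 = c1
                m = nn.ICBAM(c1)
            elif kind == "Detect":
                strides = args[0]
                c2 = 0
                m = Detect([ch[s + 1] for s in srcs], strides,
                           self.num_classes, anchors, img_size)
            else:
                raise ConfigurationError(f"unknown layer kind {kind!r}")
            layers.append((srcs, kind, m))
            ch.append(c2)
            for s in srcs:
                if s != i - 1:
                    self.save.add(s)
        self.rows = layers
        self.blocks = nn.ModuleList(m for _, _, m in layers if m is not None)
        self.detect: Detect = layers[-1][2]

    @property
    def strides(self) -> list[int]:
        return self.detect.strides

    def forward(self, x: Tensor) -> list[Tensor]:
        outputs: dict[int, Tensor] = {}
        y = x
        for i, (srcs, kind, m) in enumerate(self.rows):
            if kind == "Concat":
                y = ad.concat([y if s == i - 1 else outputs[s] for s in srcs], axis=1)
            elif kind == "Detect":
                y = m([y if s == i - 1 else outputs[s] for s in srcs])
            else:
                y = m(y if srcs[0] == i - 1 else outputs[srcs[0]])
            if i in self.save:
                outputs[i] = y
        return y

    def param_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))


@dataclass(frozen=True)
class FlopReport:
    """FLOPs of one forward pass: multiply-accumulates x 2, batch-norm folded,
    activations excluded, batch 1."""

    total_gflops: float
    per_block: tuple = field(default_factory=tuple)  # (layer index, kind, gflops)
    input_size: int = 640

    def __post_init__(self):
        s = sum(g for _, _, g in self.per_block)
        if self.per_block and abs(s - self.total_gflops) > 1e-6:
            raise ValueError("breakdown does not sum to total")


def build(variant: ModelVariant | str, seed: int = 0, anchors=None,
          img_size: int = 640) -> DetectionModel:
    """Construct an executable detection network for a variant.

    ``seed`` fixes weight initialisation (Kaiming for convolutions, BN
    weight 1 / bias 0).
    """
    if isinstance(variant, str):
        try:
            variant = VARIANTS[variant]
        except KeyError:
            raise ConfigurationError(
                f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}")
    cfg = variant_config(variant)
    with nn.init_seed(seed):
        model = DetectionModel(cfg, anchors=anchors, img_size=img_size)
    model.variant = variant
    return model


def count_flops(model: DetectionModel, input_size: int = 640) -> FlopReport:
    """Count forward-pass FLOPs at the given square input size.

    One multiply-accumulate counts as 2 FLOPs; convolution and linear layers
    only (batch-norm folds into the preceding conv, activations are free).
    Deterministic: computed from a shape-propagating forward pass on a zero
    image at batch 1.
    """
    was_training = model.training
    model.eval()
    with ad.no_grad():
        model(Tensor(np.zeros((1, 3, input_size, input_size), np.float32)))
    model.train(was_training)
    per_block = []
    total = 0.0
    for i, (_, kind, m) in enumerate(model.rows):
        if m is None:
            per_block.append((i, kind, 0.0))
            continue
        macs = sum(sub.last_macs for sub in m.modules()
                   if isinstance(sub, (nn.Conv2d, nn.Linear)))
        g = 2.0 * macs / 1e9
        per_block.append((i, kind, g))
        total += g
    return FlopReport(total_gflops=total, per_block=tuple(per_block),
                      input_size=input_size)


# -- anchors -------------------------------------------------------------------

def _kmeans_iou(wh: np.ndarray, k: int, seed: int, iters: int = 50) -> np.ndarray:
    """k-means on (w, h) with 1 - IoU distance, boxes centered at origin."""
    rng = np.random.default_rng(seed)
    centers = wh[rng.choice(len(wh), size=k, replace=False)].astype(np.float64)
    boxes = np.concatenate([np.full_like(wh, 0.5), wh], axis=1)
    for _ in range(iters):
        cent_boxes = np.concatenate([np.full_like(centers, 0.5), centers], axis=1)
        d = 1.0 - pairwise_iou(boxes, cent_boxes)
        assign = d.argmin(axis=1)
        new = centers.copy()
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                new[j] = members.mean(axis=0)
        if np.allclose(new, centers):
            break
        centers = new
    return centers


def fit_anchors(boxes, strides: list[int] | None = None, k: int = 3,
                img_size: int = 640, seed: int = 0) -> dict[int, list[tuple[float, float]]]:
    """Fit k anchors per head to a collection of labeled box sizes.

    ``boxes`` is an iterable of BoundingBox or an (N, 4) center-size array in
    normalized coordinates; sizes are scaled to ``img_size`` pixels. Anchors
    are sorted ascending by area and assigned, smallest first, to the
    smallest stride. With fewer than k * heads boxes the default anchors are
    returned (scaled per stride).
    """
    strides = strides or [8, 16, 32]
    arr = np.array([b.to_array() if hasattr(b, "to_array") else np.asarray(b, float)
                    for b in boxes], dtype=np.float64).reshape(-1, 4)
    need = k * len(strides)
    if len(arr) < need:
        return {s: DEFAULT_ANCHORS[s] for s in strides}
    wh = arr[:, 2:4] * img_size
    centers = _kmeans_iou(wh, need, seed)
    order = np.argsort(centers[:, 0] * centers[:, 1])
    centers = centers[order]
    out = {}
    for i, s in enumerate(sorted(strides)):
        out[s] = [tuple(c) for c in centers[i * k:(i + 1) * k]]
    return out


# -- checkpoints ---------------------------------------------------------------

def save_checkpoint(model: DetectionModel, path, extra: dict | None = None) -> None:
    """Single-file .npz checkpoint with embedded variant metadata."""
    variant = getattr(model, "variant", VARIANTS["baseline"])
    meta = {
        "variant": {k: getattr(variant, k) for k in (
            "name", "four_head", "icbam", "gsconv_neck", "loss_kind",
            "num_classes", "width_multiple", "depth_multiple")},
        "anchors": {str(k): [list(a) for a in v] for k, v in model.detect.anchors.items()},
        "extra": extra or {},
    }
    sd = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(yaml.safe_dump(meta).encode(), dtype=np.uint8),
             **sd)


def load_checkpoint(path, seed: int = 0) -> DetectionModel:
    with np.load(path, allow_pickle=False) as z:
        meta = yaml.safe_load(bytes(z["__meta__"]).decode())
        sd = {k: z[k] for k in z.files if k != "__meta__"}
    variant = ModelVariant(**meta["variant"])
    anchors = {int(k): [tuple(a) for a in v] for k, v in meta["anchors"].items()}
    model = build(variant, seed=seed, anchors=anchors)
    model.load_state_dict(sd)
    return model
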