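"""Axis-aligned boxes, overlap measures, and the IoU-based regression losses.

Implements the bounding-box loss family used for detector training: plain
IoU, G-IoU, C-IoU, E-IoU, S-IoU, and the power-transformed alpha-S-IoU that
sharpens gradients on highly overlapping targets (dense strips of kelp seen
from above overlap constantly, which is exactly the regime where plain IoU
losses go flat).

The S-IoU loss decomposes the mismatch between a predicted box and its
ground truth into three geometric costs computed from the minimum enclosing
rectangle of the pair:

* **angle cost**  Lambda = 1 - 2 sin^2(arcsin(s_ch/d) - pi/4), where s_ch is
  the vertical offset between centers and d their distance. This equals
  2*s_cw*s_ch/d^2 (used here: same value, no arcsin, smooth at d=0).
* **distance cost**  2 - exp(-gamma*px) - exp(-gamma*py) with
  px = (s_cw/cw)^2, py = (s_ch/ch)^2, gamma = 2 - Lambda, and (cw, ch) the
  enclosing-rectangle size.
* **shape cost**  (1-exp(-Ww))^theta + (1-exp(-Wh))^theta with
  Ww = |W-Wgt|/max(W,Wgt), Wh = |H-Hgt|/max(H,Hgt).

The alpha variant raises the IoU term and the pooled penalty to the power
``alpha`` (default 3).

All loss functions run both on plain NumPy arrays and on
:class:`kyolo.autodiff.Tensor`, so the same code serves analysis and
training. Boxes are center-size ``(cx, cy, w, h)``; the last axis of array
inputs has length 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = [
    "BoundingBox",
    "EnclosureGeometry",
    "SIoUComponents",
    "LossConfig",
    "InvalidBoxError",
    "iou",
    "enclosure",
    "angle_cost",
    "distance_cost",
    "shape_cost",
    "siou_loss",
    "alpha_siou_loss",
    "giou_loss",
    "ciou_loss",
    "eiou_loss",
    "bbox_loss",
    "pairwise_iou",
    "LOSS_KINDS",
]

LOSS_KINDS = ("giou", "ciou", "eiou", "siou", "asiou")


class InvalidBoxError(ValueError):
    """Raised for boxes with non-positive width or height."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in center-size form.

    Coordinates may be normalized to [0, 1] or in pixels; the loss math is
    scale-covariant either way.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box must have positive size, got w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) with x1 <= x2, y1 <= y2."""
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "BoundingBox":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    def to_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.w, self.h], dtype=np.float64)


@dataclass(frozen=True)
class EnclosureGeometry:
    """Geometry of a box pair: enclosing rectangle and center offsets."""

    cw: float   # width of minimum enclosing rectangle
    ch: float   # height of minimum enclosing rectangle
    s_cw: float  # |horizontal center offset|
    s_ch: float  # |vertical center offset|
    d: float    # Euclidean center distance


@dataclass(frozen=True)
class SIoUComponents:
    """Decomposed S-IoU / alpha-S-IoU value for one box pair."""

    iou: float
    angle: float
    distance: float
    shape: float
    total: float


@dataclass(frozen=True)
class LossConfig:
    """Configuration of the box-regression loss family.

    kind      one of {giou, ciou, eiou, siou, asiou}
    theta     shape-attention exponent, clamped to [2, 6] (study value: 4)
    alpha     power-transform exponent; 3 for asiou, 1 otherwise
    grouping  'standard' folds the angle cost into the distance cost only
              (through gamma = 2 - Lambda, the original S-IoU); 'paper-literal'
              additionally adds the angle cost as a separate term inside the
              halved penalty
    eps       numerical guard
    """

    kind: str = "asiou"
    theta: float = 4.0
    alpha: float = field(default=None)  # type: ignore[assignment]
    grouping: str = "standard"
    eps: float = 1e-7

    def __post_init__(self):
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; expected one of {LOSS_KINDS}")
        if self.grouping not in ("standard", "paper-literal"):
            raise ValueError(f"unknown grouping {self.grouping!r}")
        object.__setattr__(self, "theta", float(min(6.0, max(2.0, self.theta))))
        if self.alpha is None:
            object.__setattr__(self, "alpha", 3.0 if self.kind == "asiou" else 1.0)
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")


# -- backend dispatch helpers --------------------------------------------------

def _is_t(x) -> bool:
    return isinstance(x, Tensor)

def _exp(x):
    return x.exp() if _is_t(x) else np.exp(x)

def _abs(x):
    return x.abs() if _is_t(x) else np.abs(x)

def _maximum(a, b):
    if _is_t(a):
        return a.maximum(b)
    if _is_t(b):
        return b.maximum(a)
    return np.maximum(a, b)

def _minimum(a, b):
    if _is_t(a):
        return a.minimum(b)
    if _is_t(b):
        return b.minimum(a)
    return np.minimum(a, b)

def _clamp_min(x, lo):
    return x.clamp(lo=lo) if _is_t(x) else np.maximum(x, lo)

def _arctan(x):
    if _is_t(x):
        # arctan via its derivative is not a Tensor primitive; compute value
        # on data and wire the gradient manually through a first-order path:
        # d/dx arctan = 1/(1+x^2). Implemented as a stop-grad correction.
        val = np.arctan(x.data)
        out = Tensor._make(val, (x,))
        if out.requires_grad:
            d = 1.0 / (1.0 + x.data ** 2)
            out._backward = lambda g: x._accum(g * d)
        return out
    return np.arctan(x)


def _split(boxes):
    return boxes[..., 0], boxes[..., 1], boxes[..., 2], boxes[..., 3]


def _validate(boxes) -> None:
    data = boxes.data if _is_t(boxes) else np.asarray(boxes)
    if data.shape[-1] != 4:
        raise InvalidBoxError("boxes must have 4 components (cx, cy, w, h)")
    if np.any(data[..., 2:] <= 0):
        raise InvalidBoxError("box width/height must be positive")


def _as_pair(a, b):
    """Accept BoundingBox or array-like; return broadcastable (..., 4) pairs."""
    if isinstance(a, BoundingBox):
        a = a.to_array()
    if isinstance(b, BoundingBox):
        b = b.to_array()
    if not _is_t(a):
        a = np.asarray(a, dtype=np.float64)
    if not _is_t(b):
        b = np.asarray(b, dtype=np.float64)
    _validate(a)
    _validate(b)
    return a, b


# -- overlap and enclosure -----------------------------------------------------

def iou(a, b, eps: float = 1e-7):
    """Intersection over union of two boxes (or broadcast box arrays)."""
    a, b = _as_pair(a, b)
    ax, ay, aw, ah = _split(a)
    bx, by, bw, bh = _split(b)
    x1 = _maximum(ax - aw * 0.5, bx - bw * 0.5)
    y1 = _maximum(ay - ah * 0.5, by - bh * 0.5)
    x2 = _minimum(ax + aw * 0.5, bx + bw * 0.5)
    y2 = _minimum(ay + ah * 0.5, by + bh * 0.5)
    iw = _clamp_min(x2 - x1, 0.0)
    ih = _clamp_min(y2 - y1, 0.0)
    inter = iw * ih
    union = aw * ah + bw * bh - inter
    out = inter / _maximum(union, eps)
    out = out.clamp(0.0, 1.0) if _is_t(out) else np.clip(out, 0.0, 1.0)
    if isinstance(out, np.ndarray) and out.ndim == 0:
        return float(out)
    return out


def pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs IoU matrix between (N, 4) and (M, 4) center-size arrays."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return np.asarray(iou(a[:, None, :], b[None, :, :]))


def enclosure(a, b) -> EnclosureGeometry:
    """Minimum enclosing rectangle and center-offset geometry of a box pair."""
    a, b = _as_pair(a, b)
    ax, ay, aw, ah = (float(v) for v in _split(a))
    bx, by, bw, bh = (float(v) for v in _split(b))
    cw = max(ax + aw / 2, bx + bw / 2) - min(ax - aw / 2, bx - bw / 2)
    ch = max(ay + ah / 2, by + bh / 2) - min(ay - ah / 2, by - bh / 2)
    s_cw = abs(bx - ax)
    s_ch = abs(by - ay)
    return EnclosureGeometry(cw=cw, ch=ch, s_cw=s_cw, s_ch=s_ch,
                             d=math.hypot(s_cw, s_ch))


# -- S-IoU cost terms ----------------------------------------------------------

def angle_cost(g: EnclosureGeometry, eps: float = 1e-7) -> float:
    """Angle cost Lambda in [0, 1]; 0 for axis-aligned offsets, 1 at 45 deg.

    Defined as 1 - 2 sin^2(arcsin(s_ch/d) - pi/4); zero when the centers
    coincide (no direction to penalize).
    """
    if g.d < eps:
        return 0.0
    return float(2.0 * g.s_cw * g.s_ch / (g.d * g.d))


def distance_cost(g: EnclosureGeometry, angle: float, eps: float = 1e-7) -> float:
    """Distance cost 2 - exp(-gamma*px) - exp(-gamma*py), gamma = 2 - Lambda."""
    if g.cw <= eps or g.ch <= eps:
        raise ValueError("enclosure has zero width/height; boxes degenerate")
    px = (g.s_cw / g.cw) ** 2
    py = (g.s_ch / g.ch) ** 2
    gamma = 2.0 - angle
    return float(2.0 - math.exp(-gamma * px) - math.exp(-gamma * py))


def shape_cost(a, b, theta: float = 4.0) -> float:
    """Shape cost (1-e^{-Ww})^theta + (1-e^{-Wh})^theta, symmetric in (a, b)."""
    a, b = _as_pair(a, b)
    aw, ah = float(a[..., 2]), float(a[..., 3])
    bw, bh = float(b[..., 2]), float(b[..., 3])
    ww = abs(aw - bw) / max(aw, bw)
    wh = abs(ah - bh) / max(ah, bh)
    return float((1.0 - math.exp(-ww)) ** theta + (1.0 - math.exp(-wh)) ** theta)


def _siou_components(a, b, cfg: LossConfig, alpha: float):
    """Scalar S-IoU / alpha-S-IoU decomposition for a single box pair."""
    i = float(np.asarray(iou(a, b, cfg.eps)))
    g = enclosure(a, b)
    ang = angle_cost(g, cfg.eps)
    dist = distance_cost(g, ang, cfg.eps)
    shp = shape_cost(a, b, cfg.theta)
    penalty = (ang + dist + shp) / 2.0 if cfg.grouping == "paper-literal" else (dist + shp) / 2.0
    total = 1.0 - i ** alpha + penalty ** alpha
    return SIoUComponents(iou=i, angle=ang, distance=dist, shape=shp, total=total)


def siou_loss(a, b, cfg: LossConfig | None = None) -> SIoUComponents:
    """S-IoU loss for one box pair: 1 - IoU + penalty (alpha = 1)."""
    cfg = cfg or LossConfig(kind="siou")
    return _siou_components(a, b, cfg, alpha=1.0)


def alpha_siou_loss(a, b, cfg: LossConfig | None = None) -> SIoUComponents:
    """alpha-S-IoU loss: 1 - IoU^alpha + penalty^alpha (alpha = 3 by default).

    With alpha = 1 this reduces exactly to :func:`siou_loss`.
    """
    cfg = cfg or LossConfig(kind="asiou")
    return _siou_components(a, b, cfg, alpha=cfg.alpha)


# -- classic IoU-loss variants (standard published definitions) ----------------

def giou_loss(a, b, eps: float = 1e-7) -> float:
    """Generalized-IoU loss: 1 - IoU + (C - U)/C with C the enclosing area."""
    a, b = _as_pair(a, b)
    i = float(np.asarray(iou(a, b, eps)))
    g = enclosure(a, b)
    aw, ah = float(a[..., 2]), float(a[..., 3])
    bw, bh = float(b[..., 2]), float(b[..., 3])
    union = aw * ah + bw * bh - _intersection_area(a, b)
    c = g.cw * g.ch
    return float(1.0 - i + (c - union) / max(c, eps))


def _intersection_area(a, b) -> float:
    ax, ay, aw, ah = (float(v) for v in _split(a))
    bx, by, bw, bh = (float(v) for v in _split(b))
    iw = max(0.0, min(ax + aw / 2, bx + bw / 2) - max(ax - aw / 2, bx - bw / 2))
    ih = max(0.0, min(ay + ah / 2, by + bh / 2) - max(ay - ah / 2, by - bh / 2))
    return iw * ih


def ciou_loss(a, b, eps: float = 1e-7) -> float:
    """Complete-IoU loss: 1 - IoU + d^2/c^2 + alpha*v (aspect-ratio term)."""
    a, b = _as_pair(a, b)
    i = float(np.asarray(iou(a, b, eps)))
    g = enclosure(a, b)
    c2 = g.cw ** 2 + g.ch ** 2 + eps
    aw, ah = float(a[..., 2]), float(a[..., 3])
    bw, bh = float(b[..., 2]), float(b[..., 3])
    v = (4.0 / math.pi ** 2) * (math.atan(bw / bh) - math.atan(aw / ah)) ** 2
    al = v / (1.0 - i + v + eps)
    return float(1.0 - i + g.d ** 2 / c2 + al * v)


def eiou_loss(a, b, eps: float = 1e-7) -> float:
    """Efficient-IoU loss: 1 - IoU + d^2/c^2 + dw^2/cw^2 + dh^2/ch^2."""
    a, b = _as_pair(a, b)
    i = float(np.asarray(iou(a, b, eps)))
    g = enclosure(a, b)
    aw, ah = float(a[..., 2]), float(a[..., 3])
    bw, bh = float(b[..., 2]), float(b[..., 3])
    c2 = g.cw ** 2 + g.ch ** 2 + eps
    return float(1.0 - i + g.d ** 2 / c2
                 + (aw - bw) ** 2 / (g.cw ** 2 + eps)
                 + (ah - bh) ** 2 / (g.ch ** 2 + eps))


# -- vectorized / differentiable family front-end ------------------------------

def bbox_loss(pred, target, cfg: LossConfig | None = None):
    """Regression loss for broadcast (..., 4) center-size boxes.

    Works on NumPy arrays and autodiff Tensors alike; gradients flow through
    ``pred`` (and ``target`` if it is a Tensor requiring grad). Returns an
    elementwise loss of the broadcast batch shape.
    """
    cfg = cfg or LossConfig()
    if isinstance(pred, BoundingBox):
        pred = pred.to_array()
    if isinstance(target, BoundingBox):
        target = target.to_array()
    eps = cfg.eps

    px_, py_, pw, ph = _split(pred)
    tx, ty, tw, th = _split(target)

    # intersection / union
    x1 = _maximum(px_ - pw * 0.5, tx - tw * 0.5)
    y1 = _maximum(py_ - ph * 0.5, ty - th * 0.5)
    x2 = _minimum(px_ + pw * 0.5, tx + tw * 0.5)
    y2 = _minimum(py_ + ph * 0.5, ty + th * 0.5)
    inter = _clamp_min(x2 - x1, 0.0) * _clamp_min(y2 - y1, 0.0)
    union = pw * ph + tw * th - inter
    i = inter / _maximum(union, eps)

    # enclosing rectangle
    cw = _maximum(px_ + pw * 0.5, tx + tw * 0.5) - _minimum(px_ - pw * 0.5, tx - tw * 0.5)
    ch = _maximum(py_ + ph * 0.5, ty + th * 0.5) - _minimum(py_ - ph * 0.5, ty - th * 0.5)
    s_cw = _abs(tx - px_)
    s_ch = _abs(ty - py_)
    d2 = s_cw * s_cw + s_ch * s_ch

    if cfg.kind == "giou":
        c_area = cw * ch
        return 1.0 - i + (c_area - union) / _maximum(c_area, eps)

    if cfg.kind == "ciou":
        c2 = cw * cw + ch * ch + eps
        v = (4.0 / math.pi ** 2) * (_arctan(tw / th) - _arctan(pw / ph)) ** 2
        al = v / (1.0 - i + v + eps)  # aspect-ratio trade-off weight
        return 1.0 - i + d2 / c2 + al * v

    if cfg.kind == "eiou":
        c2 = cw * cw + ch * ch + eps
        return (1.0 - i + d2 / c2
                + (pw - tw) ** 2 / (cw * cw + eps)
                + (ph - th) ** 2 / (ch * ch + eps))

    # siou / asiou
    angle = 2.0 * s_cw * s_ch / (d2 + eps)          # == 1 - 2 sin^2(arcsin(s_ch/d) - pi/4)
    gamma = 2.0 - angle
    rho_x = (s_cw / (cw + eps)) ** 2
    rho_y = (s_ch / (ch + eps)) ** 2
    dist = 2.0 - _exp((-1.0 * gamma) * rho_x) - _exp((-1.0 * gamma) * rho_y)
    ww = _abs(pw - tw) / _maximum(pw, tw)
    wh = _abs(ph - th) / _maximum(ph, th)
    shp = (1.0 - _exp(-1.0 * ww)) ** cfg.theta + (1.0 - _exp(-1.0 * wh)) ** cfg.theta
    if cfg.grouping == "paper-literal":
        penalty = (angle + dist + shp) * 0.5
    else:
        penalty = (dist + shp) * 0.5
    alpha = cfg.alpha if cfg.kind == "asiou" else 1.0
    if alpha == 1.0:
        return 1.0 - i + penalty
    return 1.0 - i ** alpha + penalty ** alpha
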