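"""Network building blocks for the detector family.

Contains the YOLOv5-v6.0-style primitives (CBS = conv + batch-norm + SiLU,
C3, SPPF), the CBAM attention block and its improved variant I-CBAM
(Hardswish in place of ReLU in the channel bottleneck; conv + batch-norm +
Hardswish in place of conv + sigmoid in the spatial branch), and the two
lightweight convolutions GSConv (half dense / half depthwise with a channel
shuffle) and GhostConv.

Everything is built on :mod:`kyolo.autodiff`; modules record the
multiply-accumulate count of their last forward pass so a profiler can sum
exact FLOPs without a separate symbolic pass.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ActivationSpec", "BlockSpec", "swish", "hardswish",
    "Module", "ModuleList", "Conv2d", "BatchNorm2d",
    "SiLU", "Hardswish", "Sigmoid", "ReLU", "Identity", "make_activation",
    "ConvBNAct", "Bottleneck", "C3", "SPP", "SPPF",
    "ChannelAttention", "SpatialAttention", "CBAM", "ICBAM",
    "GSConv", "GhostConv", "channel_shuffle", "Upsample2x",
    "init_seed", "conv_param_count",
]

# Batch-norm defaults follow the YOLOv5 v6.0 convention for numeric
# comparability with the reference family.
BN_EPS = 1e-3
BN_MOMENTUM = 0.03

_INIT_RNG = np.random.default_rng(0)


@contextlib.contextmanager
def init_seed(seed: int):
    """Scope a deterministic weight-initialisation stream."""
    global _INIT_RNG
    prev = _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)
    try:
        yield
    finally:
        _INIT_RNG = prev


# -- activations ---------------------------------------------------------------

def swish(x, beta: float = 1.0):
    """Swish: x * sigmoid(beta * x). Works on arrays and Tensors."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if isinstance(x, Tensor):
        return x * (x * beta).sigmoid()
    x = np.asarray(x, dtype=np.float64)
    return x / (1.0 + np.exp(-beta * x))


def hardswish(x):
    """Hardswish: 0 for x <= -3, x for x >= 3, x(x+3)/6 in between."""
    if isinstance(x, Tensor):
        return x.hardswish()
    x = np.asarray(x, dtype=np.float64)
    return np.where(x <= -3.0, 0.0, np.where(x >= 3.0, x, x * (x + 3.0) / 6.0))


@dataclass(frozen=True)
class ActivationSpec:
    kind: str = "silu"  # relu | sigmoid | silu | swish | hardswish
    beta: float = 1.0

    def __post_init__(self):
        if self.kind not in ("relu", "sigmoid", "silu", "swish", "hardswish"):
            raise ValueError(f"unknown activation {self.kind!r}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class BlockSpec:
    """Declarative description of one block in a model config."""

    kind: str
    c_in: int
    c_out: int
    kernel: int = 1
    stride: int = 1
    repeats: int = 1
    activation: ActivationSpec = field(default_factory=ActivationSpec)

    def __post_init__(self):
        if self.c_in <= 0 or self.c_out <= 0:
            raise ValueError("channel counts must be positive")
        if self.kind in ("gsconv", "ghostconv") and self.c_out % 2:
            raise ValueError(f"{self.kind} requires an even output channel count")


# -- module system -------------------------------------------------------------

class Module:
    """Tiny nn.Module analogue: parameter discovery by attribute scan."""

    training: bool = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, ModuleList):
                for m in v:
                    yield from m.modules()

    def parameters(self) -> list[Tensor]:
        out = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    out.append(v)
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Tensor):
                    out[f"{i}.{type(m).__name__}.{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    out[f"{i}.{type(m).__name__}.{k}"] = v.copy()
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.modules()):
            for k, v in list(m.__dict__.items()):
                key = f"{i}.{type(m).__name__}.{k}"
                if key in sd:
                    if isinstance(v, Tensor):
                        v.data = sd[key].astype(v.data.dtype).copy()
                    elif isinstance(v, np.ndarray):
                        v[...] = sd[key]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Hardswish(Module):
    def forward(self, x):
        return x.hardswish()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Swish(Module):
    def __init__(self, beta: float = 1.0):
        self.beta = beta

    def forward(self, x):
        return swish(x, self.beta)


def make_activation(spec: ActivationSpec) -> Module:
    table = {"relu": ReLU, "sigmoid": Sigmoid, "silu": SiLU, "hardswish": Hardswish}
    if spec.kind in table:
        return table[spec.kind]()
    return Swish(spec.beta)


def _autopad(k: int) -> int:
    return (k - 1) // 2


class Conv2d(Module):
    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, groups: int = 1, bias: bool = True):
        fan_in = c1 // groups * k * k
        bound = float(np.sqrt(2.0 / fan_in))  # Kaiming-normal scale
        w = _INIT_RNG.normal(0.0, bound, size=(c2, c1 // groups, k, k))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c2, np.float32), requires_grad=True) if bias else None
        self.stride = s
        self.padding = _autopad(k) if p is None else p
        self.groups = groups
        self.last_macs = 0

    def forward(self, x: Tensor) -> Tensor:
        out = ad.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding, groups=self.groups)
        c2, cg, kh, kw = self.weight.shape
        ho, wo = out.shape[2], out.shape[3]
        self.last_macs = kh * kw * cg * c2 * ho * wo
        return out


class Linear(Module):
    def __init__(self, c1: int, c2: int, bias: bool = True):
        bound = float(np.sqrt(2.0 / c1))
        self.weight = Tensor(_INIT_RNG.normal(0.0, bound, size=(c1, c2)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c2, np.float32), requires_grad=True) if bias else None
        self.last_macs = 0

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        self.last_macs = int(np.prod(x.shape[:-1])) * self.weight.shape[0] * self.weight.shape[1]
        return out


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = BN_EPS, momentum: float = BN_MOMENTUM):
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        return ad.batch_norm(x, self.gamma, self.beta,
                             self.running_mean, self.running_var,
                             momentum=self.momentum, eps=self.eps,
                             training=self.training)


class ConvBNAct(Module):
    """The CBS block: convolution, batch normalisation, activation (SiLU)."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, groups: int = 1,
                 act: Module | None = None):
        self.conv = Conv2d(c1, c2, k, s, p, groups=groups, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act = act if act is not None else SiLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class Bottleneck(Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True, e: float = 0.5):
        ch = int(c2 * e)
        self.cv1 = ConvBNAct(c1, ch, 1, 1)
        self.cv2 = ConvBNAct(ch, c2, 3, 1)
        self.add = shortcut and c1 == c2

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """Cross-stage partial block: split, n bottlenecks, concat, fuse."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True, e: float = 0.5):
        ch = int(c2 * e)
        self.cv1 = ConvBNAct(c1, ch, 1, 1)
        self.cv2 = ConvBNAct(c1, ch, 1, 1)
        self.cv3 = ConvBNAct(2 * ch, c2, 1, 1)
        self.m = ModuleList(Bottleneck(ch, ch, shortcut, e=1.0) for _ in range(n))

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.cv1(x)
        for b in self.m:
            y1 = b(y1)
        return self.cv3(ad.concat([y1, self.cv2(x)], axis=1))


class SPP(Module):
    """Spatial pyramid pooling with parallel kernels (reference block)."""

    def __init__(self, c1: int, c2: int, ks: tuple[int, ...] = (5, 9, 13)):
        ch = c1 // 2
        self.cv1 = ConvBNAct(c1, ch, 1, 1)
        self.cv2 = ConvBNAct(ch * (len(ks) + 1), c2, 1, 1)
        self.ks = ks

    def forward(self, x: Tensor) -> Tensor:
        x = self.cv1(x)
        pools = [ad.max_pool2d(x, k, 1, k // 2) for k in self.ks]
        return self.cv2(ad.concat([x] + pools, axis=1))


class SPPF(Module):
    """Fast SPP: three chained k=5 max-pools concatenated with the input path.

    Chaining stride-1 pools composes receptive fields, so the three stages
    reproduce parallel pools of size 5, 9 and 13 exactly.
    """

    def __init__(self, c1: int, c2: int, k: int = 5):
        ch = c1 // 2
        self.cv1 = ConvBNAct(c1, ch, 1, 1)
        self.cv2 = ConvBNAct(ch * 4, c2, 1, 1)
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        x = self.cv1(x)
        y1 = ad.max_pool2d(x, self.k, 1, self.k // 2)
        y2 = ad.max_pool2d(y1, self.k, 1, self.k // 2)
        y3 = ad.max_pool2d(y2, self.k, 1, self.k // 2)
        return self.cv2(ad.concat([x, y1, y2, y3], axis=1))


# -- attention -----------------------------------------------------------------

class ChannelAttention(Module):
    """Shared two-layer bottleneck over global max- and average-pooled
    channel vectors; branch outputs are summed and squashed by a sigmoid.

    ``act`` is the internal bottleneck activation: ReLU in classic CBAM,
    Hardswish in the improved variant.
    """

    def __init__(self, c: int, reduction: int = 16, act: Module | None = None,
                 squash: str = "sigmoid"):
        hidden = max(1, c // reduction)
        self.fc1 = Linear(c, hidden, bias=False)
        self.fc2 = Linear(hidden, c, bias=False)
        self.act = act if act is not None else ReLU()
        self.squash = squash

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))                 # (B, C)
        mx = x.max(axis=3).max(axis=2)            # (B, C)
        y = self.fc2(self.act(self.fc1(avg))) + self.fc2(self.act(self.fc1(mx)))
        y = y.sigmoid() if self.squash == "sigmoid" else y.hardswish()
        return y.reshape(b, c, 1, 1)


class SpatialAttention(Module):
    """Spatial branch: channel-wise max/mean maps -> conv [-> BN] -> squash.

    Classic CBAM uses a bare conv followed by sigmoid. The improved variant
    adds batch normalisation and replaces the sigmoid with Hardswish, so its
    output is *not* confined to (0, 1): the minimum attainable weight is
    -0.375 (the Hardswish minimum, at pre-activation -1.5).
    """

    def __init__(self, kernel: int = 7, improved: bool = False):
        if kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = Conv2d(2, 1, kernel, 1, kernel // 2, bias=not improved)
        self.bn = BatchNorm2d(1) if improved else Identity()
        self.squash = Hardswish() if improved else Sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        mx = x.max(axis=1, keepdims=True)
        avg = x.mean(axis=1, keepdims=True)
        return self.squash(self.bn(self.conv(ad.concat([mx, avg], axis=1))))


class CBAM(Module):
    """Classic sequential channel-then-spatial attention."""

    improved = False

    def __init__(self, c: int, reduction: int = 16, kernel: int = 7):
        self.ca = ChannelAttention(c, reduction, act=ReLU())
        self.sa = SpatialAttention(kernel, improved=False)

    def forward(self, x: Tensor) -> Tensor:
        x = x * self.ca(x)
        return x * self.sa(x)


class ICBAM(CBAM):
    """Improved CBAM: Hardswish channel bottleneck; conv+BN+Hardswish spatial
    branch. The channel branch keeps its final sigmoid (only the two stated
    changes are made); pass ``channel_squash='hardswish'`` to change it too.
    """

    improved = True

    def __init__(self, c: int, reduction: int = 16, kernel: int = 7,
                 channel_squash: str = "sigmoid"):
        self.ca = ChannelAttention(c, reduction, act=Hardswish(), squash=channel_squash)
        self.sa = SpatialAttention(kernel, improved=True)


# -- lightweight convolutions --------------------------------------------------

def channel_shuffle(x: Tensor, groups: int = 2) -> Tensor:
    """Interleave channel groups: [a, b, c, d] with 2 groups -> [a, c, b, d]."""
    b, c, h, w = x.shape
    if c % groups:
        raise ValueError("channels must divide evenly into groups")
    return (x.reshape(b, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(b, c, h, w))


class GSConv(Module):
    """Half-dense, half-depthwise convolution with channel shuffle.

    A dense conv produces c_out/2 channels; a depthwise conv (default 5x5)
    re-processes them into another c_out/2; the two halves are concatenated
    and shuffled so dense- and depthwise-derived channels interleave.
    """

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, dw_k: int = 5):
        if c2 % 2:
            raise ValueError("GSConv output channels must be even")
        ch = c2 // 2
        self.cv1 = ConvBNAct(c1, ch, k, s)
        self.cv2 = ConvBNAct(ch, ch, dw_k, 1, groups=ch)
        self.groups = 2

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.cv1(x)
        y2 = self.cv2(y1)
        return channel_shuffle(ad.concat([y1, y2], axis=1), self.groups)


class GhostConv(Module):
    """Ghost convolution: dense primary features plus cheap depthwise ghosts."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, dw_k: int = 5):
        if c2 % 2:
            raise ValueError("GhostConv output channels must be even")
        ch = c2 // 2
        self.cv1 = ConvBNAct(c1, ch, k, s)
        self.cv2 = ConvBNAct(ch, ch, dw_k, 1, groups=ch)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        return ad.concat([y, self.cv2(y)], axis=1)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.upsample_nearest2x(x)


def conv_param_count(c1: int, c2: int, k: int, groups: int = 1, bias: bool = False) -> int:
    """Parameters of a bare convolution (closed form, for comparisons)."""
    return c2 * (c1 // groups) * k * k + (c2 if bias else 0)
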