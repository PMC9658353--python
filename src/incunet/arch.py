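"""The network family and the convolution cost model.

Five segmentation families are built from declarative specs:

* ``baseline_unet`` — plain two-conv U-Net blocks at every stage;
* ``mi_unet`` — inception blocks at every stage, with large-kernel-heavy
  blocks (Inc.Block 1: 1x1/3x3/5x5/7x7, most filters on 5x5 and 7x7) at the
  high-resolution levels and small-kernel-heavy blocks (Inc.Block 2:
  1x1/3x3/5x5, most filters on 3x3) at the deep levels;
* ``ds_mi_unet`` — the same with every k x k (k>1) convolution factored into
  depthwise + pointwise;
* ``hybrid`` — plain blocks on the encoder, inception blocks on the decoder;
* ``ds_hybrid`` — the hybrid with depthwise-separable convolutions;

plus a ``classifier`` family: a 9-weight-layer CNN (five 3x3 conv stages of
32/64/128/256/512 filters, then four dense layers down to one sigmoid unit)
that flags tumor-bearing slices from the FLAIR+T2 channels.

The analytical cost model counts multiplications for a same-padded stride-1
convolution on a P x Q map: standard Y1 = Uw*Uh*C*D*P^2 and separable
Y2 = Uw*Uh*C*P^2 + C*D*P^2, whose ratio is 1/D + 1/(Uw*Uh).
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dense,
    DepthwiseConv2d,
    MaxPool2d,
    Module,
    SeparableConv2d,
    Tensor,
    concatenate,
)
from .nn.autograd import from_op

FAMILIES = ("baseline_unet", "mi_unet", "ds_mi_unet", "hybrid", "ds_hybrid", "classifier")

__all__ = [
    "ConvCostSpec",
    "BlockSpec",
    "ModelSpec",
    "InitSpec",
    "standard_conv_cost",
    "ds_conv_cost",
    "ds_cost_ratio",
    "build_block",
    "build_model",
    "count_parameters",
    "count_multiplies",
    "init_weights",
    "describe_model",
    "FAMILIES",
]


# -- cost model ---------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ConvCostSpec:
    """Symbols of the convolution cost formulas: Uw x Uh kernel, C input
    channels, D output channels, P x Q feature map (square maps, P == Q)."""

    uw: int
    uh: int
    c: int
    d: int
    p: int
    q: int | None = None

    def __post_init__(self):
        q = self.p if self.q is None else self.q
        object.__setattr__(self, "q", q)
        for name in ("uw", "uh", "c", "d", "p", "q"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.p != self.q:
            raise ValueError(f"cost formulas assume square maps, got P={self.p}, Q={self.q}")


def standard_conv_cost(spec: ConvCostSpec) -> int:
    """Multiplies of a standard convolution: Uw * Uh * C * D * P^2."""
    return spec.uw * spec.uh * spec.c * spec.d * spec.p**2


def ds_conv_cost(spec: ConvCostSpec) -> int:
    """Multiplies of a depthwise-separable convolution:
    depthwise Uw*Uh*C*P^2 plus pointwise C*D*P^2."""
    return spec.uw * spec.uh * spec.c * spec.p**2 + spec.c * spec.d * spec.p**2


def ds_cost_ratio(spec: ConvCostSpec, exact: bool = False) -> float | Fraction:
    """Separable/standard multiply ratio: 1/D + 1/(Uw*Uh).

    Independent of C and P.  With D = 1 and a 1x1 kernel the ratio is 2 —
    the factored convolution costs *more* when only a single feature map is
    produced; the saving appears as D and the kernel grow.
    """
    ratio = Fraction(1, spec.d) + Fraction(1, spec.uw * spec.uh)
    return ratio if exact else float(ratio)


# -- declarative specs --------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class BlockSpec:
    """One stage block: parallel inception branches or a plain conv pair.

    For ``plain_conv`` the "branches" are applied sequentially (the classic
    two 3x3 convolutions of a U-Net stage); for the inception kinds they are
    parallel and channel-concatenated.
    """

    kind: str  # plain_conv | inception_1 | inception_2
    branch_kernels: tuple[tuple[int, int], ...]
    branch_filters: tuple[int, ...]
    ds: bool = False
    batch_norm: bool = True

    def __post_init__(self):
        if self.kind not in ("plain_conv", "inception_1", "inception_2"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if len(self.branch_kernels) != len(self.branch_filters):
            raise ValueError("branch_kernels and branch_filters must have equal length")
        if any(f < 0 for f in self.branch_filters):
            raise ValueError("branch filters must be non-negative")
        by_kernel = dict(zip(self.branch_kernels, self.branch_filters))
        if self.kind == "inception_1":
            large = sum(f for k, f in by_kernel.items() if max(k) >= 5)
            small = by_kernel.get((3, 3), 0)
            if large <= small:
                raise ValueError("inception_1 must allocate more filters to 5x5/7x7 than to 3x3")
        if self.kind == "inception_2":
            if (7, 7) in by_kernel:
                raise ValueError("inception_2 has no 7x7 branch")
            large = sum(f for k, f in by_kernel.items() if max(k) >= 5)
            small = by_kernel.get((3, 3), 0)
            if small <= large:
                raise ValueError("inception_2 must allocate more filters to 3x3 than to 5x5")

    @property
    def out_channels(self) -> int:
        return int(sum(self.branch_filters))

    @staticmethod
    def plain(filters: int, ds: bool = False, batch_norm: bool = True) -> "BlockSpec":
        return BlockSpec("plain_conv", ((3, 3), (3, 3)), (filters, filters), ds, batch_norm)

    @staticmethod
    def inception_1(filters: int, ds: bool = False, batch_norm: bool = True) -> "BlockSpec":
        """Large-kernel-heavy block: (1x1, 3x3, 5x5, 7x7) filters split
        (f/8, f/8, 3f/8, 3f/8)."""
        if filters < 8:
            raise ValueError("inception_1 needs at least 8 filters")
        n3 = filters // 8
        n5 = 3 * filters // 8
        n7 = 3 * filters // 8
        n1 = filters - n3 - n5 - n7
        return BlockSpec(
            "inception_1", ((1, 1), (3, 3), (5, 5), (7, 7)), (n1, n3, n5, n7), ds, batch_norm
        )

    @staticmethod
    def inception_2(filters: int, ds: bool = False, batch_norm: bool = True) -> "BlockSpec":
        """Small-kernel-heavy block: (1x1, 3x3, 5x5) filters split (f/4, f/2, f/4)."""
        if filters < 4:
            raise ValueError("inception_2 needs at least 4 filters")
        n3 = filters // 2
        n5 = filters // 4
        n1 = filters - n3 - n5
        return BlockSpec("inception_2", ((1, 1), (3, 3), (5, 5)), (n1, n3, n5), ds, batch_norm)

    @staticmethod
    def for_kind(kind: str, filters: int, ds: bool = False) -> "BlockSpec":
        if kind == "plain_conv":
            return BlockSpec.plain(filters, ds)
        if kind == "inception_1":
            return BlockSpec.inception_1(filters, ds)
        if kind == "inception_2":
            return BlockSpec.inception_2(filters, ds)
        raise ValueError(f"unknown block kind {kind!r}")


@dataclasses.dataclass(frozen=True)
class InitSpec:
    """Gaussian weight initialization V_ij ~ N(mu, sigma)."""

    mu: float = 0.0
    sigma: float = 0.01

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one architecture.

    ``stage_blocks`` may override the per-stage block kinds as a mapping with
    keys ``encoder`` (list of kinds, shallow to deep), ``bottleneck`` (kind)
    and ``decoder`` (list of kinds, deep to shallow); by default the family
    decides, placing large-kernel inception blocks at high-resolution levels
    and small-kernel ones at depth.
    """

    family: str = "ds_hybrid"
    in_channels: int = 4
    depth: int = 4
    base_filters: int = 16
    stage_blocks: dict | None = None
    out_activation: str = "sigmoid"
    encoder_residual: bool | None = None
    full_scale_skips: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.in_channels <= 0:
            raise ValueError("in_channels must be positive")
        if self.family != "classifier" and self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.out_activation != "sigmoid":
            raise ValueError("only sigmoid output is supported")

    @property
    def ds(self) -> bool:
        return self.family.startswith("ds_")

    def resolved_encoder_residual(self) -> bool:
        if self.encoder_residual is not None:
            return self.encoder_residual
        return self.ds  # residual-dense wiring ships with the ds families

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        return ModelSpec(**d)


def _default_stage_kinds(family: str, depth: int) -> dict:
    """Kind per resolution level: levels 0-1 get Inc.Block 1 (high spatial
    feature concentration), deeper levels Inc.Block 2, mirrored on the
    decoder; plain blocks where the family says so."""

    def inception_kind(level: int) -> str:
        return "inception_1" if level < 2 else "inception_2"

    if family == "baseline_unet":
        enc = ["plain_conv"] * depth
        mid = "plain_conv"
        dec = ["plain_conv"] * depth
    elif family in ("mi_unet", "ds_mi_unet"):
        enc = [inception_kind(i) for i in range(depth)]
        mid = inception_kind(depth)
        dec = [inception_kind(level) for level in range(depth - 1, -1, -1)]
    elif family in ("hybrid", "ds_hybrid"):
        enc = ["plain_conv"] * depth
        mid = "plain_conv"
        dec = [inception_kind(level) for level in range(depth - 1, -1, -1)]
    else:  # pragma: no cover
        raise ValueError(family)
    return {"encoder": enc, "bottleneck": mid, "decoder": dec}


# -- blocks -------------------------------------------------------------------


def _make_conv(in_ch: int, out_ch: int, kernel, ds: bool, bias: bool) -> Module:
    if ds and max(kernel) > 1:
        return SeparableConv2d(in_ch, out_ch, kernel, bias=bias)
    return Conv2d(in_ch, out_ch, kernel, bias=bias)


class PlainConvBlock(Module):
    """Two sequential 3x3 convolutions, each followed by (BN +) ReLU."""

    def __init__(self, in_channels: int, spec: BlockSpec):
        super().__init__()
        if spec.kind != "plain_conv":
            raise ValueError("PlainConvBlock requires a plain_conv spec")
        f1, f2 = spec.branch_filters
        bias = not spec.batch_norm
        self.conv1 = _make_conv(in_channels, f1, spec.branch_kernels[0], spec.ds, bias)
        self.conv2 = _make_conv(f1, f2, spec.branch_kernels[1], spec.ds, bias)
        self.bn1 = BatchNorm2d(f1) if spec.batch_norm else None
        self.bn2 = BatchNorm2d(f2) if spec.batch_norm else None
        self.first_channels = f1
        self.out_channels = f2

    def forward(self, x: Tensor, inject: Tensor | None = None) -> Tensor:
        h = self.conv1(x)
        if inject is not None:
            h = h + inject
        if self.bn1 is not None:
            h = self.bn1(h)
        h = h.relu()
        h = self.conv2(h)
        if self.bn2 is not None:
            h = self.bn2(h)
        return h.relu()


class InceptionBlock(Module):
    """Parallel branches of different kernel sizes, channel-concatenated,
    batch-normalized after the merge, then ReLU."""

    def __init__(self, in_channels: int, spec: BlockSpec):
        super().__init__()
        if spec.kind not in ("inception_1", "inception_2"):
            raise ValueError("InceptionBlock requires an inception spec")
        bias = not spec.batch_norm
        self.branches = [
            _make_conv(in_channels, f, k, spec.ds, bias)
            for k, f in zip(spec.branch_kernels, spec.branch_filters)
            if f > 0
        ]
        self.bn = BatchNorm2d(spec.out_channels) if spec.batch_norm else None
        self.first_channels = spec.out_channels
        self.out_channels = spec.out_channels

    def forward(self, x: Tensor, inject: Tensor | None = None) -> Tensor:
        h = concatenate([b(x) for b in self.branches], axis=1)
        if inject is not None:
            h = h + inject
        if self.bn is not None:
            h = self.bn(h)
        return h.relu()


def build_block(spec: BlockSpec, in_channels: int) -> Module:
    """Instantiate a stage block; maps (N, in_channels, H, W) to
    (N, spec.out_channels, H, W) with same-padding throughout."""
    if spec.kind == "plain_conv":
        return PlainConvBlock(in_channels, spec)
    return InceptionBlock(in_channels, spec)


def _nearest_upsample(x: Tensor, factor: int) -> Tensor:
    data = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)
    out = from_op(data, (x,))
    n, c, h, w = x.data.shape

    def bwd(g):
        x._accumulate(
            g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        )

    out._backward = bwd
    return out


# -- models -------------------------------------------------------------------


class UNetModel(Module):
    """Encoder-decoder with ``depth`` poolings/upsamplings and skip
    connections; optional residual-dense encoder wiring (the first conv of
    encoder block 0, pooled and 1x1-projected, added into the first conv of
    every later encoder block) and optional full-scale skips."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        kinds = spec.stage_blocks or _default_stage_kinds(spec.family, spec.depth)
        widths = [spec.base_filters * 2**i for i in range(spec.depth + 1)]

        self.enc_blocks: list[Module] = []
        in_ch = spec.in_channels
        for i in range(spec.depth):
            block = build_block(BlockSpec.for_kind(kinds["encoder"][i], widths[i], spec.ds), in_ch)
            self.enc_blocks.append(block)
            in_ch = block.out_channels
        self.pool = MaxPool2d()
        self.bottleneck = build_block(
            BlockSpec.for_kind(kinds["bottleneck"], widths[spec.depth], spec.ds), in_ch
        )

        self.residual = spec.resolved_encoder_residual()
        if self.residual:
            src_ch = self.enc_blocks[0].first_channels
            self.res_proj = [
                Conv2d(src_ch, self.enc_blocks[i].first_channels, 1, bias=False)
                for i in range(1, spec.depth)
            ]
        else:
            self.res_proj = []

        self.upconvs: list[Module] = []
        self.dec_blocks: list[Module] = []
        in_ch = self.bottleneck.out_channels
        for j in range(spec.depth):
            level = spec.depth - 1 - j
            up = ConvTranspose2d(in_ch, widths[level])
            skip_ch = self.enc_blocks[level].out_channels
            cat_ch = widths[level] + skip_ch
            if spec.full_scale_skips:
                cat_ch += sum(
                    self.enc_blocks[l].out_channels for l in range(spec.depth) if l != level
                )
            block = build_block(BlockSpec.for_kind(kinds["decoder"][j], widths[level], spec.ds), cat_ch)
            self.upconvs.append(up)
            self.dec_blocks.append(block)
            in_ch = block.out_channels
        self.head = Conv2d(in_ch, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        step = 2**self.spec.depth
        if h % step or w % step:
            raise ValueError(f"input spatial size {(h, w)} must be divisible by {step}")

        skips: list[Tensor] = []
        first_feat: Tensor | None = None
        cur = x
        for i, block in enumerate(self.enc_blocks):
            inject = None
            if self.residual and i > 0:
                pooled = first_feat
                for _ in range(i):
                    pooled = self.pool(pooled)
                inject = self.res_proj[i - 1](pooled)
            if i > 0 or not self.residual:
                out = block.forward(cur, inject=inject)
            else:
                # capture the first conv features before the block nonlinearity
                if isinstance(block, PlainConvBlock):
                    feat = block.conv1(cur)
                    h1 = feat + 0.0
                    if block.bn1 is not None:
                        h1 = block.bn1(h1)
                    h1 = h1.relu()
                    h2 = block.conv2(h1)
                    if block.bn2 is not None:
                        h2 = block.bn2(h2)
                    out = h2.relu()
                else:
                    feat = concatenate([b(cur) for b in block.branches], axis=1)
                    h1 = feat
                    if block.bn is not None:
                        h1 = block.bn(h1)
                    out = h1.relu()
                first_feat = feat
            skips.append(out)
            cur = self.pool(out)
        cur = self.bottleneck(cur)

        for j, (up, block) in enumerate(zip(self.upconvs, self.dec_blocks)):
            level = self.spec.depth - 1 - j
            cur = up(cur)
            parts = [cur, skips[level]]
            if self.spec.full_scale_skips:
                for l in range(self.spec.depth):
                    if l == level:
                        continue
                    feat = skips[l]
                    if l < level:  # shallower: pool down to this level
                        for _ in range(level - l):
                            feat = self.pool(feat)
                    else:  # deeper: nearest-neighbor upsample
                        feat = _nearest_upsample(feat, 2 ** (l - level))
                    parts.append(feat)
            cur = block(concatenate(parts, axis=1))
        return self.head(cur).sigmoid()


class ClassifierNet(Module):
    """Slice-level tumor/no-tumor CNN: five 3x3 conv stages (filters
    base*1,2,4,8,16 — 32/64/128/256/512 at the default base of 32), each with
    ReLU and 2x2 max pooling, then global average pooling and four dense
    layers ending in one sigmoid unit; nine weight layers in total."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        base = spec.base_filters
        widths = [base * 2**i for i in range(5)]
        self.convs: list[Module] = []
        in_ch = spec.in_channels
        for wd in widths:
            self.convs.append(Conv2d(in_ch, wd, 3))
            in_ch = wd
        self.pool = MaxPool2d()
        d1 = max(in_ch // 4, 4)
        d2 = max(in_ch // 16, 2)
        self.dense = [Dense(in_ch, d1), Dense(d1, d2), Dense(d2, max(d2 // 2, 2))]
        self.out = Dense(max(d2 // 2, 2), 1)

    def forward(self, x: Tensor) -> Tensor:
        cur = x
        for conv in self.convs:
            cur = conv(cur).relu()
            if min(cur.data.shape[2], cur.data.shape[3]) >= 2:
                cur = self.pool(cur)
        cur = cur.mean(axis=(2, 3))  # global average pooling
        for d in self.dense:
            cur = d(cur).relu()
        return self.out(cur).sigmoid()


def build_model(spec: ModelSpec) -> Module:
    """Build a network from its declarative spec."""
    if spec.family == "classifier":
        return ClassifierNet(spec)
    return UNetModel(spec)


# -- introspection ------------------------------------------------------------


def count_parameters(model: Module) -> int:
    """Total number of trainable scalars."""
    return int(sum(p.size for p in model.parameters()))


def count_multiplies(model: Module, input_shape: tuple[int, ...]) -> int:
    """Forward multiply count for one sample, from the analytical cost model.

    Runs a dummy forward pass to record per-layer feature-map sizes, then
    sums Uw*Uh*C*D*P*Q per standard convolution, Uw*Uh*C*P*Q per depthwise
    pass, C*D*P*Q per pointwise pass, 4*C*D*P*Q per 2x transposed
    convolution, and in*out per dense layer.
    """
    model.eval()
    model(Tensor(np.zeros((1, *input_shape))))
    model.train()
    total = 0
    for m in model.modules():
        if isinstance(m, Conv2d) and m.last_input_hw is not None:
            h, w = m.last_input_hw
            kh, kw = m.kernel_size
            total += kh * kw * m.in_channels * m.out_channels * h * w
        elif isinstance(m, DepthwiseConv2d) and m.last_input_hw is not None:
            h, w = m.last_input_hw
            kh, kw = m.kernel_size
            total += kh * kw * m.channels * h * w
        elif isinstance(m, ConvTranspose2d):
            pass  # handled below via recorded input sizes
        elif isinstance(m, Dense):
            total += m.in_features * m.out_features
    # transposed convs do not record shapes; derive from the model spec
    for m in model.modules():
        if isinstance(m, ConvTranspose2d) and getattr(m, "last_input_hw", None):
            h, w = m.last_input_hw
            total += 4 * m.in_channels * m.out_channels * h * w
    return int(total)


def _fans(m: Module, shape: tuple[int, ...]) -> tuple[int, int]:
    from .nn.layers import Conv2d, ConvTranspose2d, Dense, DepthwiseConv2d

    if isinstance(m, Conv2d):
        d, c, kh, kw = shape
        return c * kh * kw, d * kh * kw
    if isinstance(m, DepthwiseConv2d):
        _, kh, kw = shape
        return kh * kw, kh * kw
    if isinstance(m, ConvTranspose2d):
        return shape[0], shape[1]
    if isinstance(m, Dense):
        return shape[0], shape[1]
    n = int(np.prod(shape))
    return n, n


def init_weights(model: Module, init: InitSpec = InitSpec(), seed: int = 0,
                 scheme: str = "normal") -> Module:
    """Seeded weight initialization; biases zero, batch-norm left at identity.

    ``scheme="normal"`` draws every convolution/dense weight i.i.d. from
    N(mu, sigma) — the initialization prescribed for the segmentation
    networks.  ``scheme="glorot"`` uses Glorot-uniform, the customary
    default for a plain CNN classifier, where the tiny fixed-sigma draw
    would let activations die across nine layers.
    """
    if scheme not in ("normal", "glorot"):
        raise ValueError(f"unknown init scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    for m in model.modules():
        weight = getattr(m, "weight", None)
        if isinstance(weight, Tensor) and weight.is_weight:
            if scheme == "normal":
                weight.data = rng.normal(init.mu, init.sigma, size=weight.data.shape)
            else:
                fan_in, fan_out = _fans(m, weight.data.shape)
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                weight.data = rng.uniform(-limit, limit, size=weight.data.shape)
        bias = getattr(m, "bias", None)
        if isinstance(bias, Tensor):
            bias.data = np.zeros_like(bias.data)
    return model


def describe_model(spec: ModelSpec, input_hw: tuple[int, int] = (176, 176)) -> pd.DataFrame:
    """Per-layer table: kernel, channels, map size, parameters and multiply
    costs (standard formula for full convs, separable formula split across
    the depthwise/pointwise rows)."""
    model = build_model(spec)
    model.eval()
    model(Tensor(np.zeros((1, spec.in_channels, *input_hw))))
    rows = []
    for m in model.modules():
        if isinstance(m, Conv2d) and m.last_input_hw is not None:
            h, w = m.last_input_hw
            kh, kw = m.kernel_size
            rows.append(
                dict(layer="conv", kernel=f"{kh}x{kw}", in_channels=m.in_channels,
                     out_channels=m.out_channels, height=h, width=w,
                     parameters=int(sum(p.size for p in m.parameters())),
                     multiplies=kh * kw * m.in_channels * m.out_channels * h * w)
            )
        elif isinstance(m, DepthwiseConv2d) and m.last_input_hw is not None:
            h, w = m.last_input_hw
            kh, kw = m.kernel_size
            rows.append(
                dict(layer="depthwise", kernel=f"{kh}x{kw}", in_channels=m.channels,
                     out_channels=m.channels, height=h, width=w,
                     parameters=int(sum(p.size for p in m.parameters())),
                     multiplies=kh * kw * m.channels * h * w)
            )
        elif isinstance(m, ConvTranspose2d) and getattr(m, "last_input_hw", None):
            h, w = m.last_input_hw
            rows.append(
                dict(layer="upconv", kernel="2x2", in_channels=m.in_channels,
                     out_channels=m.out_channels, height=h, width=w,
                     parameters=int(sum(p.size for p in m.parameters())),
                     multiplies=4 * m.in_channels * m.out_channels * h * w)
            )
        elif isinstance(m, Dense):
            rows.append(
                dict(layer="dense", kernel="-", in_channels=m.in_features,
                     out_channels=m.out_features, height=1, width=1,
                     parameters=int(sum(p.size for p in m.parameters())),
                     multiplies=m.in_features * m.out_features)
            )
    return pd.DataFrame(rows)
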