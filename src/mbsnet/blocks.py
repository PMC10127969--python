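"""Computational blocks of the multi-branch segmentation network.

The network combines a local-detail encoder built from parallel residual
mixers (PRM) with squeeze-and-excitation gating, a shallow global encoder
built from multi-grid dilated convolution blocks with a softmax spatial
attention module, and a decoder that cross-fuses the two feature streams
(FCFB).  Every block is shape-preserving in H and W; downsampling happens
only in the pooling layers between encoder levels.

Public ``forward`` methods take and return channel-first (N, C, H, W)
feature maps.  Internally all arithmetic runs channel-last; composite blocks
and the full network chain the ``forward_nhwc`` methods directly so layout
conversion happens only at the outer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from . import nn


@dataclass(frozen=True)
class ConvSpec:
    """Specification of a shape-preserving convolution-norm-activation unit."""

    in_channels: int
    out_channels: int
    kernel: int = 3
    dilation: int = 1
    use_norm: bool = True
    activation: str = "relu"

    def __post_init__(self):
        if self.kernel not in (1, 3):
            raise ValueError(f"kernel must be 1 or 3, got {self.kernel}")
        if self.dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {self.dilation}")
        if self.activation not in ("relu", "gelu", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")

    @property
    def padding(self) -> int:
        return self.dilation * (self.kernel - 1) // 2


@dataclass(frozen=True)
class DilationSpec:
    """Multi-grid dilation schedule: per-block rates are r * multi_grid[i]."""

    rate_multiplier: int = 2
    multi_grid: tuple = (1, 2, 4)

    def __post_init__(self):
        if self.rate_multiplier < 1 or any(m < 1 for m in self.multi_grid):
            raise ValueError("dilation rates must be >= 1")
        if len(self.multi_grid) != 3:
            raise ValueError("multi_grid must have exactly 3 entries")

    @property
    def rates(self) -> tuple:
        return tuple(self.rate_multiplier * m for m in self.multi_grid)


class NHWCModule(nn.Module):
    """Base for blocks computing channel-last with a channel-first interface."""

    def forward_nhwc(self, x):
        raise NotImplementedError

    def forward(self, x):
        x = ag.as_tensor(x)
        return ag.nhwc_to_nchw(self.forward_nhwc(ag.nchw_to_nhwc(x)))


def _nhwc(module, x):
    """Apply a module in channel-last layout (Identity lacks forward_nhwc)."""
    fn = getattr(module, "forward_nhwc", None)
    return fn(x) if fn is not None else module(x)


class ConvBNAct(NHWCModule):
    """Convolution followed by batch normalization and an activation.

    In training mode the normalization uses per-channel batch statistics; in
    inference mode it uses the running statistics accumulated during training.
    """

    def __init__(self, spec: ConvSpec, rng=None):
        super().__init__()
        self.spec = spec
        self.conv = nn.Conv2d(spec.in_channels, spec.out_channels, spec.kernel,
                              dilation=spec.dilation, bias=not spec.use_norm, rng=rng)
        self.norm = nn.BatchNorm2d(spec.out_channels) if spec.use_norm else nn.Identity()
        self.act = {"relu": nn.ReLU, "gelu": nn.GELU, "none": nn.Identity}[spec.activation]()

    def forward_nhwc(self, x):
        if x.shape[3] != self.spec.in_channels:
            raise ValueError(
                f"ConvBNAct: expected {self.spec.in_channels} input channels, "
                f"received {x.shape[3]}")
        return self.act(self.norm(self.conv(x)))


def conv_bn_act(x, spec: ConvSpec, rng=None):
    """Functional form of :class:`ConvBNAct` with freshly initialized weights."""
    return ConvBNAct(spec, rng=rng)(x)


class PRM(NHWCModule):
    """Parallel residual mixer.

    Two parallel paths refine the input: a stride-1 max-pooled path passed
    through a convolution, and a pointwise + depthwise convolution path with
    channel layer normalization and GELU.  The paths are concatenated, fused
    by a 3x3 convolution back to C channels, and added to the input.
    """

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.channels = channels
        self.pool_conv = ConvBNAct(ConvSpec(channels, channels, kernel=3), rng=rng)
        self.pw_conv = ConvBNAct(ConvSpec(channels, channels, kernel=1), rng=rng)
        self.dw_conv = nn.DepthwiseConv2d(channels, kernel=3, bias=True, rng=rng)
        self.dw_norm = nn.LayerNormChannels(channels)
        self.fuse = ConvBNAct(ConvSpec(2 * channels, channels, kernel=3), rng=rng)

    def forward_nhwc(self, x):
        x = ag.as_tensor(x)
        if not np.isfinite(x.data).all():
            raise ValueError("PRM: non-finite values in input")
        if x.shape[3] != self.channels:
            raise ValueError(f"PRM: expected {self.channels} channels, received {x.shape[3]}")
        pooled = self.pool_conv.forward_nhwc(ag.maxpool3x3_s1(x))
        local = ag.gelu(self.dw_norm(self.dw_conv(self.pw_conv.forward_nhwc(x))))
        return ag.add(self.fuse.forward_nhwc(ag.concat([pooled, local], axis=3)), x)


def prm_forward(x, block: "PRM"):
    return block(x)


class DilatedBlock(NHWCModule):
    """1x1 conv -> dilated 3x3 conv -> 1x1 conv, each with BN + ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rate: int, rng=None):
        super().__init__()
        if rate < 1:
            raise ValueError(f"dilation rate must be >= 1, got {rate}")
        self.rate = rate
        self.reduce = ConvBNAct(ConvSpec(in_channels, out_channels, kernel=1), rng=rng)
        self.dilated = ConvBNAct(ConvSpec(out_channels, out_channels, kernel=3,
                                          dilation=rate), rng=rng)
        self.expand = ConvBNAct(ConvSpec(out_channels, out_channels, kernel=1), rng=rng)

    def forward_nhwc(self, x):
        return self.expand.forward_nhwc(
            self.dilated.forward_nhwc(self.reduce.forward_nhwc(x)))


def dilated_block_forward(x, block: "DilatedBlock"):
    return block(x)


class SEBlock(NHWCModule):
    """Squeeze-and-excitation channel gate."""

    def __init__(self, channels: int, reduction: int = 4, rng=None):
        super().__init__()
        if reduction > channels:
            raise ValueError(f"reduction {reduction} exceeds channel count {channels}")
        if channels % reduction != 0:
            raise ValueError(f"channels {channels} not divisible by reduction {reduction}")
        self.channels = channels
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)

    def forward_nhwc(self, x):
        n, c = x.shape[0], x.shape[3]
        g = ag.global_avg_pool(x)                       # (N, C)
        gate = ag.sigmoid(self.fc2(ag.relu(self.fc1(g))))
        return ag.mul(x, ag.reshape(gate, (n, 1, 1, c)))


def se_forward(x, block: "SEBlock"):
    return block(x)


class SpatialAttention(NHWCModule):
    """Softmax channel-context spatial attention with a residual connection.

    A global descriptor (adaptive average pool) is mapped through a two-layer
    bottleneck (C -> C/4 -> C, GELU in between) and softmaxed over channels,
    yielding attention weights a with sum_c a_c = 1.  A 1x1 value convolution
    V of the input is contracted against a to produce a single-channel spatial
    context map, which is broadcast-added to every channel of the input.
    """

    def __init__(self, channels: int, reduction: int = 4, rng=None):
        super().__init__()
        self.channels = channels
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)
        self.value = nn.Conv2d(channels, channels, kernel=1, bias=True, rng=rng)

    def channel_attention(self, x):
        """Softmax attention weights over channels, shape (N, C); x is NHWC."""
        g = ag.global_avg_pool(x)                       # (N, C)
        return ag.softmax(self.fc2(ag.gelu(self.fc1(g))), axis=1)

    def forward_nhwc(self, x):
        x = ag.as_tensor(x)
        n, c = x.shape[0], x.shape[3]
        if c != self.channels:
            raise ValueError(f"SpatialAttention: expected {self.channels} channels, "
                             f"received {c}")
        a = self.channel_attention(x)
        v = self.value(x)
        context = ag.tsum(ag.mul(v, ag.reshape(a, (n, 1, 1, c))), axis=3, keepdims=True)
        return ag.add(x, context)


def sam_forward(x, block: "SpatialAttention"):
    return block(x)


class UpConv(NHWCModule):
    """3x3 conv (BN + ReLU) followed by x2 bilinear upsampling."""

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        self.conv = ConvBNAct(ConvSpec(in_channels, out_channels, kernel=3), rng=rng)

    def forward_nhwc(self, x):
        return ag.upsample_bilinear2x(self.conv.forward_nhwc(x))


def upconv_forward(x, block: "UpConv"):
    return block(x)


class FCFB(nn.Module):
    """Feature cross-fusion block.

    Each stream is channel-projected and bilinearly upsampled x2, then the
    upsampled convolution of the *other* stream is added:

        O_G = up(proj_g(y_g)) + upconv_l(y_l)
        O_L = up(proj_l(y_l)) + upconv_g(y_g)
    """

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.upconv_g = UpConv(in_channels, out_channels, rng=rng)
        self.upconv_l = UpConv(in_channels, out_channels, rng=rng)
        self.proj_g = ConvBNAct(ConvSpec(in_channels, out_channels, kernel=1), rng=rng)
        self.proj_l = ConvBNAct(ConvSpec(in_channels, out_channels, kernel=1), rng=rng)

    def forward_nhwc(self, y_g, y_l):
        if tuple(y_g.shape) != tuple(y_l.shape):
            raise ValueError(
                f"FCFB: stream shapes differ: {tuple(y_g.shape)} vs {tuple(y_l.shape)}")
        o_g = ag.add(ag.upsample_bilinear2x(self.proj_g.forward_nhwc(y_g)),
                     self.upconv_l.forward_nhwc(y_l))
        o_l = ag.add(ag.upsample_bilinear2x(self.proj_l.forward_nhwc(y_l)),
                     self.upconv_g.forward_nhwc(y_g))
        return o_g, o_l

    def forward(self, y_g, y_l):
        y_g = ag.nchw_to_nhwc(ag.as_tensor(y_g))
        y_l = ag.nchw_to_nhwc(ag.as_tensor(y_l))
        o_g, o_l = self.forward_nhwc(y_g, y_l)
        return ag.nhwc_to_nchw(o_g), ag.nhwc_to_nchw(o_l)


def fcfb_forward(y_g, y_l, block: "FCFB"):
    return block(y_g, y_l)
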