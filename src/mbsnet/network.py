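"""Assembly of the three-branch segmentation network.

Branch L (local): five conv + PRM + SE levels (16, 32, 64, 128, 256 channels)
with 2x2 max pooling between levels.  Branch G (global): three multi-grid
dilated blocks (16, 32, 64 channels, rates 2/4/8) with 2x2 average pooling
between blocks, fusing the matching-level branch-L output into each block's
input, and a spatial attention module on the final output.  Branch F
(fusion): decodes L with skip connections down to 1/4 scale, then cross-fuses
the L and G streams over two x2 upsampling stages and predicts one logit
channel at full resolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from . import nn
from .blocks import (FCFB, PRM, ConvBNAct, ConvSpec, DilatedBlock,
                     DilationSpec, SEBlock, SpatialAttention, UpConv, _nhwc)


@dataclass(frozen=True)
class MBSNetConfig:
    in_channels: int = 3
    l_channels: tuple = (16, 32, 64, 128, 256)
    g_channels: tuple = (16, 32, 64)
    dilation: DilationSpec = dataclasses.field(default_factory=DilationSpec)
    use_dilated: bool = True
    use_prm: bool = True
    use_se: bool = True
    use_sam: bool = True
    use_branch_l: bool = True
    use_branch_g: bool = True
    use_fcfb: bool = True
    se_reduction: int = 4
    decoder_channels: tuple = (128, 64)
    head_channels: int = 16
    input_size: tuple = (320, 320)
    seed: int = 0

    def __post_init__(self):
        if len(self.l_channels) != 5 or any(
                a >= b for a, b in zip(self.l_channels, self.l_channels[1:])):
            raise ValueError("l_channels must be strictly increasing with length 5")
        if len(self.g_channels) != 3:
            raise ValueError("g_channels must have length 3")
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(f"input size {self.input_size} must be divisible by 16")
        if not (self.use_branch_l or self.use_branch_g):
            raise ValueError("at least one encoder branch must be enabled")
        if self.g_channels[-1] != self.decoder_channels[-1] and self.use_branch_l \
                and self.use_branch_g:
            raise ValueError("fusion requires g_channels[-1] == decoder_channels[-1]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["dilation"] = {"rate_multiplier": self.dilation.rate_multiplier,
                         "multi_grid": list(self.dilation.multi_grid)}
        return json.dumps(d)

    @staticmethod
    def from_json(s: str) -> "MBSNetConfig":
        d = json.loads(s)
        d["dilation"] = DilationSpec(d["dilation"]["rate_multiplier"],
                                     tuple(d["dilation"]["multi_grid"]))
        for key in ("l_channels", "g_channels", "decoder_channels", "input_size"):
            d[key] = tuple(d[key])
        return MBSNetConfig(**d)


class MBSNet(nn.Module):
    def __init__(self, config: MBSNetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        lc = config.l_channels
        gc = config.g_channels
        rates = config.dilation.rates if config.use_dilated else (1, 1, 1)

        # ---- branch L -----------------------------------------------------
        if config.use_branch_l:
            prev = config.in_channels
            for i, c in enumerate(lc):
                setattr(self, f"l_conv{i}", ConvBNAct(ConvSpec(prev, c, kernel=3), rng=rng))
                setattr(self, f"l_prm{i}",
                        PRM(c, rng=rng) if config.use_prm else nn.Identity())
                setattr(self, f"l_se{i}",
                        SEBlock(c, config.se_reduction, rng=rng)
                        if config.use_se else nn.Identity())
                prev = c

        # ---- branch G -----------------------------------------------------
        if config.use_branch_g:
            prev = config.in_channels
            for i, c in enumerate(gc):
                fuse_in = prev + (lc[i] if config.use_branch_l else 0)
                setattr(self, f"g_fuse{i}", ConvBNAct(ConvSpec(fuse_in, c, kernel=1), rng=rng))
                setattr(self, f"g_block{i}", DilatedBlock(c, c, rates[i], rng=rng))
                prev = c
            self.g_sam = (SpatialAttention(gc[-1], rng=rng)
                          if config.use_sam else nn.Identity())

        # ---- branch F (decoder) -------------------------------------------
        d0, d1 = config.decoder_channels
        if config.use_branch_l:
            self.f_up1 = UpConv(lc[4], d0, rng=rng)
            self.f_skip1 = ConvBNAct(ConvSpec(d0 + lc[3], d0, kernel=3), rng=rng)
            self.f_up2 = UpConv(d0, d1, rng=rng)
            self.f_skip2 = ConvBNAct(ConvSpec(d1 + lc[2], d1, kernel=3), rng=rng)

        streams = int(config.use_branch_l) + int(config.use_branch_g)
        if streams == 2 and config.use_fcfb:
            self.f_fcfb1 = FCFB(d1, d1, rng=rng)
            self.f_fcfb2 = FCFB(d1, d1, rng=rng)
        else:
            if config.use_branch_l:
                self.f_l_up1 = UpConv(d1, d1, rng=rng)
                self.f_l_up2 = UpConv(d1, d1, rng=rng)
            if config.use_branch_g:
                self.f_g_up1 = UpConv(gc[-1], d1, rng=rng)
                self.f_g_up2 = UpConv(d1, d1, rng=rng)

        head_in = streams * d1
        self.head_conv = ConvBNAct(ConvSpec(head_in, config.head_channels, kernel=3), rng=rng)
        self.head_out = nn.Conv2d(config.head_channels, 1, kernel=1, bias=True, rng=rng)

    # ----------------------------------------------------------------------
    def forward(self, images):
        cfg = self.config
        x = ag.as_tensor(images)
        if x.ndim != 4 or x.shape[1] != cfg.in_channels:
            raise ValueError(
                f"expected input (n, {cfg.in_channels}, H, W), got {tuple(x.shape)}")
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(f"input spatial size {(h, w)} must be divisible by 16")

        if x.requires_grad or x._prev:
            x = ag.nchw_to_nhwc(x)                      # channel-last internally
        else:  # plain input images: convert outside the graph
            x = ag.Tensor(np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)))

        l_feats = []
        if cfg.use_branch_l:
            cur = x
            for i in range(5):
                cur = getattr(self, f"l_conv{i}").forward_nhwc(cur)
                cur = _nhwc(getattr(self, f"l_prm{i}"), cur)
                cur = _nhwc(getattr(self, f"l_se{i}"), cur)
                l_feats.append(cur)
                if i < 4:
                    cur = ag.maxpool2x2(cur)

        g_out = None
        if cfg.use_branch_g:
            cur = x
            for i in range(3):
                if cfg.use_branch_l:
                    cur = ag.concat([cur, l_feats[i]], axis=3)
                cur = getattr(self, f"g_fuse{i}").forward_nhwc(cur)
                cur = getattr(self, f"g_block{i}").forward_nhwc(cur)
                if i < 2:
                    cur = ag.avgpool2x2(cur)
            g_out = _nhwc(self.g_sam, cur)              # (n, H/4, W/4, gc[-1])

        l_out = None
        if cfg.use_branch_l:
            d = self.f_up1.forward_nhwc(l_feats[4])     # H/16 -> H/8
            d = self.f_skip1.forward_nhwc(ag.concat([d, l_feats[3]], axis=3))
            d = self.f_up2.forward_nhwc(d)              # H/8 -> H/4
            l_out = self.f_skip2.forward_nhwc(ag.concat([d, l_feats[2]], axis=3))

        if l_out is not None and g_out is not None:
            if cfg.use_fcfb:
                g_out, l_out = self.f_fcfb1.forward_nhwc(g_out, l_out)
                g_out, l_out = self.f_fcfb2.forward_nhwc(g_out, l_out)
            else:
                l_out = self.f_l_up2.forward_nhwc(self.f_l_up1.forward_nhwc(l_out))
                g_out = self.f_g_up2.forward_nhwc(self.f_g_up1.forward_nhwc(g_out))
            fused = ag.concat([g_out, l_out], axis=3)
        elif l_out is not None:
            fused = self.f_l_up2.forward_nhwc(self.f_l_up1.forward_nhwc(l_out))
        else:
            fused = self.f_g_up2.forward_nhwc(self.f_g_up1.forward_nhwc(g_out))

        logits = self.head_out(self.head_conv.forward_nhwc(fused))
        return ag.nhwc_to_nchw(logits)                  # (n, 1, H, W) logits


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def build_mbsnet(config: MBSNetConfig | None = None) -> MBSNet:
    return MBSNet(config or MBSNetConfig())


def forward(net: MBSNet, images) -> ag.Tensor:
    return net(images)


def count_parameters(net: nn.Module) -> int:
    return net.num_parameters()


def count_macs(net: MBSNet, input_size=None) -> float:
    """Multiply-accumulate count of conv and linear layers for one image.

    Normalization, activation and pooling are not counted.  Returns raw MACs;
    divide by 1e9 for the conventional 'G' unit.
    """
    if input_size is None:
        input_size = net.config.input_size
    h, w = (input_size, input_size) if isinstance(input_size, int) else input_size
    counter: list = []
    was_training = net.training
    net.eval()
    try:
        with ag.no_grad(), ag.count_macs_into(counter):
            net(np.zeros((1, net.config.in_channels, h, w), dtype=np.float32))
    finally:
        net.train(was_training)
    return float(sum(counter))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(net: MBSNet, path, extra: dict | None = None):
    state = net.state_dict()
    state["__config__"] = np.frombuffer(
        net.config.to_json().encode(), dtype=np.uint8).copy()
    if extra:
        state["__extra__"] = np.frombuffer(
            json.dumps(extra).encode(), dtype=np.uint8).copy()
    with open(path, "wb") as fh:
        np.savez(fh, **state)


def load_checkpoint(path) -> tuple[MBSNet, dict]:
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    config = MBSNetConfig.from_json(bytes(state.pop("__config__")).decode())
    extra = {}
    if "__extra__" in state:
        extra = json.loads(bytes(state.pop("__extra__")).decode())
    net = MBSNet(config)
    net.load_state_dict(state)
    return net, extra
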