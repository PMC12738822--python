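"""Small-Neck: a P2..P5 bidirectional feature pyramid for small targets.

The neck extends the usual P3..P5 pyramid down to the stride-4 P2 level,
fuses levels with *fast normalised fusion* (non-negative learnable weights
normalised by their sum plus a small constant), and replaces standard
convolutions with the cheaper GSConv / VoVGSCSP blocks.  Deep-level widths
are pruned, since in dense small-target imagery the coarse P5 features
carry comparatively little information.

Topology (one top-down then one bottom-up sweep):

* laterals: 1x1 conv+BN projecting each backbone tap to the level width;
* top-down nodes fuse the lateral with the upsampled coarser feature;
* bottom-up nodes fuse the lateral (same-level skip edge), the top-down
  intermediate and the downsampled finer output — the node at P5 has no
  separate top-down intermediate and takes two inputs;
* each fusion is followed by a VoVGSCSP block; resampling uses
  nearest-neighbour x2 upsampling (with a 1x1 GSConv width projection) and
  stride-2 3x3 GSConv downsampling.

An *ablation* variant (`use_gsconv=False, use_vovgscsp=False`) swaps every
GS block for a plain 3x3 conv+BN and, with `level_widths=None`, keeps the
unpruned backbone tap widths — the plain a-BiFPN used for comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, astensor, concat
from .nn import BatchNorm2d, Conv2d, Module, Sequential, SiLU, Upsample2x, parameter

__all__ = ["NeckConfig", "FusionNode", "fast_fusion", "GSConv", "VoVGSCSP",
           "SmallNeck", "ConvBNAct", "channel_shuffle"]

LEVELS = ("P2", "P3", "P4", "P5")

#: default per-level widths: P3/P4 follow the s100 backbone taps, P5 pruned
DEFAULT_LEVEL_WIDTHS = {"P2": 32, "P3": 40, "P4": 80, "P5": 112}


@dataclass
class NeckConfig:
    levels: tuple = LEVELS
    level_widths: dict | None = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_WIDTHS))  # None -> tap widths (unpruned)
    pruned_channels: int = 256         # upper bound applied to every level width
    use_gsconv: bool = True
    use_vovgscsp: bool = True
    xi: float = 1e-4

    def resolve_widths(self, in_channels: dict) -> dict:
        widths = dict(self.level_widths) if self.level_widths is not None else {
            lv: in_channels[lv] for lv in self.levels}
        return {lv: min(w, self.pruned_channels) for lv, w in widths.items()}


class ConvBNAct(Module):
    """Conv (no bias) + BN + SiLU — the standard detector conv block."""

    def __init__(self, cin, cout, k=1, stride=1, groups=1, act=True, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU() if act else None

    def forward(self, x):
        x = self.bn(self.conv(x))
        return self.act(x) if self.act else x


def channel_shuffle(x, groups: int = 2):
    """Interleave `groups` channel blocks: (g, c/g) -> (c/g, g) ordering."""
    x = astensor(x)
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError("channel count must divide by groups")
    return x.reshape(n, groups, c // groups, h, w).transpose(0, 2, 1, 3, 4).reshape(n, c, h, w)


class GSConv(Module):
    """Half standard conv + half depthwise conv, concatenated and shuffled."""

    def __init__(self, cin, cout, k=1, stride=1, rng=None):
        super().__init__()
        if cout % 2:
            raise ValueError("GSConv output width must be even")
        half = cout // 2
        self.cv1 = ConvBNAct(cin, half, k, stride=stride, rng=rng)
        self.cv2 = ConvBNAct(half, half, 5, groups=half, rng=rng)
        self.cout = cout

    def forward(self, x):
        a = self.cv1(x)
        b = self.cv2(a)
        return channel_shuffle(concat([a, b], axis=1), 2)


class GSBottleneck(Module):
    def __init__(self, c, rng=None):
        super().__init__()
        self.g1 = GSConv(c, c, 1, rng=rng)
        self.g2 = GSConv(c, c, 3, rng=rng)

    def forward(self, x):
        return x + self.g2(self.g1(x))


class VoVGSCSP(Module):
    """Cross-stage-partial block with GSConv bottlenecks on one branch."""

    def __init__(self, cin, cout, n=1, rng=None):
        super().__init__()
        half = cout // 2
        self.cv1 = ConvBNAct(cin, half, 1, rng=rng)
        self.cv2 = ConvBNAct(cin, half, 1, rng=rng)
        self.blocks = Sequential(*[GSBottleneck(half, rng=rng) for _ in range(n)])
        self.cv3 = ConvBNAct(2 * half, cout, 1, rng=rng)
        self.cout = cout

    def forward(self, x):
        return self.cv3(concat([self.blocks(self.cv1(x)), self.cv2(x)], axis=1))


class PlainBlock(Module):
    """3x3 conv+BN block used by the non-GS ablation neck."""

    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        super().__init__()
        self.cv = ConvBNAct(cin, cout, k, stride=stride, rng=rng)

    def forward(self, x):
        return self.cv(x)


class FusionNode(Module):
    """Fast normalised fusion: relu(w_i)-weighted mean of same-shape inputs."""

    def __init__(self, n_inputs: int, xi: float = 1e-4):
        super().__init__()
        self.n_inputs = n_inputs
        self.xi = xi
        self.weights = parameter((n_inputs,), "ones")

    def coefficients(self) -> np.ndarray:
        w = np.maximum(self.weights.data, 0.0)
        return w / (w.sum() + self.xi)

    def forward(self, inputs):
        if len(inputs) != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {len(inputs)}")
        shapes = {tuple(astensor(t).shape) for t in inputs}
        if len(shapes) != 1:
            raise ValueError(f"fusion inputs must share a shape, got {sorted(shapes)}")
        w = self.weights.maximum(Tensor(np.zeros(self.n_inputs, dtype=np.float32)))
        denom = w.sum() + self.xi
        out = None
        for i, t in enumerate(inputs):
            term = astensor(t) * (w[i] / denom)
            out = term if out is None else out + term
        return out


def fast_fusion(inputs, node: FusionNode):
    """Functional alias for ``node(inputs)``."""
    return node(inputs)


class SmallNeck(Module):
    """a-BiFPN over P2..P5 with GSConv/VoVGSCSP blocks and width pruning."""

    def __init__(self, in_channels: dict, cfg: NeckConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or NeckConfig()
        self.cfg = cfg
        rng = rng or np.random.default_rng(0)
        missing = [lv for lv in cfg.levels if lv not in in_channels]
        if missing:
            raise ValueError(f"backbone taps missing levels {missing}")
        self.widths = cfg.resolve_widths(in_channels)
        W = self.widths
        gs = cfg.use_gsconv
        vov = (lambda ci, co: VoVGSCSP(ci, co, rng=rng)) if cfg.use_vovgscsp else \
              (lambda ci, co: PlainBlock(ci, co, rng=rng))
        proj = (lambda ci, co, k=1, s=1: GSConv(ci, co, k, s, rng=rng)) if gs else \
               (lambda ci, co, k=1, s=1: ConvBNAct(ci, co, 3 if s == 2 else k, stride=s, rng=rng))

        self.lateral = {lv: ConvBNAct(in_channels[lv], W[lv], 1, act=False, rng=rng)
                        for lv in cfg.levels}
        self.up = Upsample2x()
        # top-down path
        self.up_proj = {lv: proj(W[up], W[lv]) for lv, up in
                        (("P4", "P5"), ("P3", "P4"), ("P2", "P3")) if W[up] != W[lv]}
        self.td_fuse = {lv: FusionNode(2, cfg.xi) for lv in ("P4", "P3", "P2")}
        self.td_block = {lv: vov(W[lv], W[lv]) for lv in ("P4", "P3", "P2")}
        # bottom-up path
        self.down_proj = {lv: proj(W[dn], W[lv], 3, 2) for lv, dn in
                          (("P3", "P2"), ("P4", "P3"), ("P5", "P4"))}
        self.bu_fuse = {"P3": FusionNode(3, cfg.xi), "P4": FusionNode(3, cfg.xi),
                        "P5": FusionNode(2, cfg.xi)}
        self.bu_block = {lv: vov(W[lv], W[lv]) for lv in ("P3", "P4", "P5")}
        self.out_channels = {lv: W[lv] for lv in cfg.levels}

    def _resize_up(self, x, lv):
        x = self.up(x)
        return self.up_proj[lv](x) if lv in self.up_proj else x

    def forward(self, feats: dict) -> dict:
        missing = [lv for lv in self.cfg.levels if lv not in feats]
        if missing:
            raise ValueError(f"neck input missing levels {missing}")
        lat = {lv: self.lateral[lv](feats[lv]) for lv in self.cfg.levels}
        td4 = self.td_block["P4"](self.td_fuse["P4"]([lat["P4"], self._resize_up(lat["P5"], "P4")]))
        td3 = self.td_block["P3"](self.td_fuse["P3"]([lat["P3"], self._resize_up(td4, "P3")]))
        out2 = self.td_block["P2"](self.td_fuse["P2"]([lat["P2"], self._resize_up(td3, "P2")]))
        out3 = self.bu_block["P3"](self.bu_fuse["P3"](
            [lat["P3"], td3, self.down_proj["P3"](out2)]))
        out4 = self.bu_block["P4"](self.bu_fuse["P4"](
            [lat["P4"], td4, self.down_proj["P4"](out3)]))
        out5 = self.bu_block["P5"](self.bu_fuse["P5"](
            [lat["P5"], self.down_proj["P5"](out4)]))
        return {"P2": out2, "P3": out3, "P4": out4, "P5": out5}


def neck_forward(feats: dict, neck: SmallNeck) -> dict:
    """Functional alias for ``neck(feats)``."""
    return neck(feats)
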