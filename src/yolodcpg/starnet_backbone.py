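"""StarNet backbone: star-operation blocks in a 4-stage hierarchy.

The *star operation* multiplies two pointwise linear expansions of a feature
map element-wise, giving cheap high-order channel interactions; spatial
mixing is delegated to 7x7 depthwise convolutions.  Batch normalisation
follows the depthwise convolutions and ReLU6 is the only activation, which
keeps the backbone friendly to integer-arithmetic edge deployment.

Stage ``i`` halves the spatial size and doubles the width, so a stem at
stride 2 followed by four stages yields pyramid taps P2/P3/P4/P5 at strides
4/8/16/32 with widths ``base_width * 2**i``.  The `s100` variant
(``base_width=20``, depths 1/2/4/1, expansion 4) is the default detection
backbone; `s050` and `s150` scale it down/up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, astensor
from .nn import BatchNorm2d, Conv2d, Identity, Module, ReLU6, Sequential

__all__ = ["StarNetConfig", "StarBlock", "StarNet", "build_backbone",
           "backbone_forward", "STARNET_VARIANTS"]

#: (base_width, stage_depths, mlp_ratio) of the reference variants
STARNET_VARIANTS = {
    "s050": (16, (1, 1, 3, 1), 3),
    "s100": (20, (1, 2, 4, 1), 4),
    "s150": (24, (1, 2, 4, 2), 3),
}

LEVELS = ("P2", "P3", "P4", "P5")
STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32}


@dataclass
class StarNetConfig:
    variant: str = "s100"
    base_width: int | None = None
    stage_depths: tuple | None = None
    mlp_ratio: int | None = None
    stem_width: int = 32
    dw_kernel: int = 7

    def resolved(self):
        if self.variant not in STARNET_VARIANTS:
            raise ValueError(f"unknown StarNet variant '{self.variant}'")
        b, d, m = STARNET_VARIANTS[self.variant]
        return (self.base_width or b, tuple(self.stage_depths or d), self.mlp_ratio or m)


class ConvBN(Module):
    """Convolution (with bias) optionally followed by batch normalisation."""

    def __init__(self, cin, cout, k=1, stride=1, groups=1, with_bn=True, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, groups=groups, bias=True, rng=rng)
        self.bn = BatchNorm2d(cout) if with_bn else Identity()

    def forward(self, x):
        return self.bn(self.conv(x))


class StarBlock(Module):
    """Depthwise mixing -> dual pointwise expansion -> ReLU6-gated product
    -> pointwise projection -> depthwise conv -> residual add."""

    def __init__(self, dim, mlp_ratio=4, dw_kernel=7, rng=None):
        super().__init__()
        self.dim = dim
        self.dwconv = ConvBN(dim, dim, dw_kernel, groups=dim, with_bn=True, rng=rng)
        self.f1 = ConvBN(dim, mlp_ratio * dim, 1, with_bn=False, rng=rng)
        self.f2 = ConvBN(dim, mlp_ratio * dim, 1, with_bn=False, rng=rng)
        self.g = ConvBN(mlp_ratio * dim, dim, 1, with_bn=True, rng=rng)
        self.dwconv2 = ConvBN(dim, dim, dw_kernel, groups=dim, with_bn=False, rng=rng)
        self.act = ReLU6()

    def forward(self, x):
        x = astensor(x)
        if x.shape[1] != self.dim:
            raise ValueError(f"StarBlock expects {self.dim} channels, got {x.shape[1]}")
        identity = x
        x = self.dwconv(x)
        x = self.act(self.f1(x)) * self.f2(x)  # the star operation
        x = self.dwconv2(self.g(x))
        return identity + x


class StarNet(Module):
    def __init__(self, cfg: StarNetConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or StarNetConfig()
        self.cfg = cfg
        base, depths, mlp = cfg.resolved()
        rng = rng or np.random.default_rng(0)
        self.stem = Sequential(ConvBN(3, cfg.stem_width, 3, stride=2, rng=rng), ReLU6())
        self.stages = []
        prev = cfg.stem_width
        self.widths = {}
        for i, depth in enumerate(depths):
            dim = base * 2 ** i
            layers = [ConvBN(prev, dim, 3, stride=2, rng=rng), ReLU6()]
            layers += [StarBlock(dim, mlp, cfg.dw_kernel, rng=rng) for _ in range(depth)]
            self.stages.append(Sequential(*layers))
            self.widths[LEVELS[i]] = dim
            prev = dim
        self.out_channels = dict(self.widths)

    def forward(self, img):
        img = astensor(img)
        if img.ndim != 4 or img.shape[1] != 3:
            raise ValueError("expected an (n, 3, h, w) image tensor")
        h, w = img.shape[2], img.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input spatial size {h}x{w} must be divisible by 32")
        x = self.stem(img)
        feats = {}
        for level, stage in zip(LEVELS, self.stages):
            x = stage(x)
            feats[level] = x
        return feats


def build_backbone(cfg: StarNetConfig | str | None = None, seed: int = 0) -> StarNet:
    """Construct a StarNet backbone from a config or a variant name."""
    if isinstance(cfg, str):
        cfg = StarNetConfig(variant=cfg)
    return StarNet(cfg, rng=np.random.default_rng(seed))


def backbone_forward(img, backbone: StarNet):
    """Run the backbone, returning the P2..P5 pyramid (strides 4/8/16/32)."""
    return backbone(img)
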