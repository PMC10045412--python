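"""Building blocks: ghost convolutions with switchable normalization and
the residual / dense modules assembled from them.

A ghost block (GBS) spends an ordinary convolution on only ``out/s``
"intrinsic" feature maps and manufactures the remaining ``out - out/s``
"ghost" maps with a cheap depthwise operation, cutting the parameter
count by roughly the ratio ``s``.  Every block normalizes with SN, so
the stack stays usable at batch sizes down to 1.

* GBS  — primary 1x1 conv -> depthwise cheap op -> concat -> SN
* RGS  — ResNet-style bottleneck of GBS units with an additive skip
* RGM  — a stage of stacked RGS; the stage entry may downsample x2
* DGS  — GBS (+ SN-ReLU) consuming the concatenation of all previous
         outputs, emitting a fixed growth-rate number of channels
* DGM  — ``n`` cascaded DGS, output channels = input + n * growth
* CSR  — plain Conv2d -> SN -> ReLU stem
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Module, Conv2d, DepthwiseConv2d, Tensor, concat
from .normalization import SwitchableNorm2d

__all__ = ["GhostConfig", "StageSpec", "ghost_param_count", "conv_param_count",
           "GhostBlockSN", "ResidualGhostSN", "ResidualGhostModule",
           "DenseGhostSN", "DenseGhostModule", "CSR"]


@dataclass(frozen=True)
class GhostConfig:
    in_channels: int
    out_channels: int
    ratio: int = 2           # s: primary conv produces out/s intrinsic maps
    primary_kernel: int = 1
    cheap_kernel: int = 3

    def __post_init__(self):
        if self.ratio < 2:
            raise ValueError("ghost ratio must be >= 2")
        if self.out_channels % self.ratio:
            raise ValueError("out_channels must be divisible by ratio")


@dataclass(frozen=True)
class StageSpec:
    """Encoder/decoder layout: residual-stage depths and widths, and the
    dense-module depths used in each decoder branch."""

    rgs_counts: tuple[int, ...] = (1, 2, 3, 1)
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    dgm_counts: tuple[int, int] = (8, 4)
    growth: int = 32

    def __post_init__(self):
        if len(self.rgs_counts) != len(self.stage_channels):
            raise ValueError("rgs_counts and stage_channels lengths differ")


def ghost_param_count(cfg: GhostConfig) -> int:
    """Closed-form conv-weight count of a ghost block (no biases):
    primary C*(O/s)*k_p^2 plus cheap depthwise (O/s)*(s-1)*k_c^2
    = C*O/s * k_p^2 + (s-1)/s * O * k_c^2."""
    intrinsic = cfg.out_channels // cfg.ratio
    return (cfg.in_channels * intrinsic * cfg.primary_kernel ** 2
            + intrinsic * (cfg.ratio - 1) * cfg.cheap_kernel ** 2)


def conv_param_count(module: Module) -> int:
    """Total weight count of the convolution layers inside ``module``
    (SN scale/shift/logit parameters excluded)."""
    total = 0
    for name, p in module.named_parameters():
        if name.endswith("weight"):
            total += p.data.size
    return total


class GhostBlockSN(Module):
    """Ghost block: 1x1 primary conv for the intrinsic maps, depthwise
    cheap op (channel multiplier s-1) for the ghost maps, concatenated
    and switchable-normalized."""

    def __init__(self, cfg: GhostConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        intrinsic = cfg.out_channels // cfg.ratio
        self.primary = Conv2d(cfg.in_channels, intrinsic, cfg.primary_kernel,
                              rng=rng)
        self.cheap = DepthwiseConv2d(intrinsic, cfg.cheap_kernel,
                                     multiplier=cfg.ratio - 1, rng=rng)
        self.sn = SwitchableNorm2d(cfg.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        intrinsic = self.primary(x)
        ghost = self.cheap(intrinsic)
        return self.sn(concat([intrinsic, ghost], axis=1))


class CSR(Module):
    """Conv2d -> SN -> ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size,
                           stride=stride, rng=rng)
        self.sn = SwitchableNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.sn(self.conv(x)).relu()


class ResidualGhostSN(Module):
    """RGS: bottleneck GBS -> depthwise 3x3 (carrying any stride) ->
    GBS, with an additive identity skip (1x1-projected when the shape
    changes) and ReLU after the addition."""

    def __init__(self, in_channels: int, out_channels: int, rng,
                 stride: int = 1, ratio: int = 2):
        super().__init__()
        mid = max(out_channels // 2, ratio)
        mid += mid % ratio
        self.gbs1 = GhostBlockSN(GhostConfig(in_channels, mid, ratio), rng)
        self.mid_dw = DepthwiseConv2d(mid, 3, stride=stride, rng=rng)
        self.mid_sn = SwitchableNorm2d(mid)
        self.gbs2 = GhostBlockSN(GhostConfig(mid, out_channels, ratio), rng)
        self.stride = stride
        if stride != 1 or in_channels != out_channels:
            self.proj = Conv2d(in_channels, out_channels, 1, stride=stride,
                               rng=rng)
            self.proj_sn = SwitchableNorm2d(out_channels)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.gbs1(x).relu()
        y = self.mid_sn(self.mid_dw(y)).relu()
        y = self.gbs2(y)
        skip = x if self.proj is None else self.proj_sn(self.proj(x))
        return (y + skip).relu()


class ResidualGhostModule(Module):
    """RGM: ``n_blocks`` stacked RGS; the first block changes width and
    optionally downsamples x2 (stage entry)."""

    def __init__(self, in_channels: int, out_channels: int, n_blocks: int,
                 rng, stride: int = 1):
        super().__init__()
        blocks = [ResidualGhostSN(in_channels, out_channels, rng, stride=stride)]
        blocks += [ResidualGhostSN(out_channels, out_channels, rng)
                   for _ in range(n_blocks - 1)]
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


class DenseGhostSN(Module):
    """DGS: ghost block over the concatenated preceding features,
    followed by SN-ReLU, emitting ``growth`` channels."""

    def __init__(self, in_channels: int, growth: int, rng):
        super().__init__()
        self.gbs = GhostBlockSN(GhostConfig(in_channels, growth), rng)
        self.sn = SwitchableNorm2d(growth)

    def forward(self, feats: list[Tensor]) -> Tensor:
        x = feats[0] if len(feats) == 1 else concat(feats, axis=1)
        return self.sn(self.gbs(x)).relu()


class DenseGhostModule(Module):
    """DGM: ``n`` cascaded DGS with dense forward connectivity; every
    DGS sees the module input and all previous DGS outputs, and the
    module returns their full concatenation (input + n * growth
    channels)."""

    def __init__(self, in_channels: int, n: int, growth: int, rng):
        super().__init__()
        if n < 1:
            raise ValueError("a dense module needs at least one DGS")
        self.out_channels = in_channels + n * growth
        self.blocks = [DenseGhostSN(in_channels + i * growth, growth, rng)
                       for i in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for block in self.blocks:
            feats.append(block(feats))
        return concat(feats, axis=1)
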