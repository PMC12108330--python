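"""Feature-extraction branch: star-operation blocks inside a U-Net encoder.

Each encoder stage is 3x3 conv -> Star Block(s) -> 3x3 conv (the stage's
skip feature) followed by 2x2 max pooling; channel width doubles per stage.
A Star Block expands the feature into two parallel branches and fuses them by
element-wise multiplication (the "star" operation), which realises implicit
high-order channel interactions at the cost of plain convolutions:

    F = Conv( ReLU6(Conv(DW(X))) * ReLU6(Conv(DW(X))) )

with a trailing depth-wise separable convolution and batch normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class StarBlockConfig:
    channels: int = 32
    expansion_factor: int = 4
    dw_kernel: int = 7
    activation: str = "relu6"
    residual: bool = False  # the printed form has no shortcut; flag for ablation

    def __post_init__(self):
        if self.dw_kernel % 2 == 0 or self.dw_kernel < 1:
            raise ValueError("dw_kernel must be odd and positive")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")


@dataclass
class EncoderConfig:
    base_width: int = 32
    num_stages: int = 4
    star_blocks_per_stage: int = 1
    star: StarBlockConfig = None

    def __post_init__(self):
        if self.num_stages != 4:
            raise ValueError("the encoder is fixed at four stages")
        if self.star is None:
            self.star = StarBlockConfig(channels=self.base_width)

    def stage_width(self, stage_index: int) -> int:
        if not 1 <= stage_index <= self.num_stages:
            raise ValueError(f"stage_index must be 1..{self.num_stages}")
        return self.base_width * 2 ** (stage_index - 1)


def _activation(name: str):
    if name.lower() == "relu6":
        return nn.relu6
    if name.lower() == "gelu":
        return nn.gelu
    raise ValueError(f"unknown activation {name!r}")


class StarBlock(nn.Module):
    def __init__(self, config: StarBlockConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.config = config
        c, e, k = config.channels, config.expansion_factor, config.dw_kernel
        self.act = _activation(config.activation)
        self.dw_in = nn.DepthwiseConv2d(c, k, rng, dtype=dtype)
        self.expand_a = nn.Conv2d(c, e * c, 1, rng, dtype=dtype)
        self.expand_b = nn.Conv2d(c, e * c, 1, rng, dtype=dtype)
        self.reduce = nn.Conv2d(e * c, c, 1, rng, dtype=dtype)
        self.dw_out = nn.SeparableConv2d(c, c, k, rng, dtype=dtype)
        self.bn = nn.BatchNorm2d(c, dtype=dtype)

    @property
    def product_channels(self) -> int:
        return self.config.expansion_factor * self.config.channels

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.config.channels:
            raise ValueError(
                f"star block expects {self.config.channels} channels, got {x.shape[1]}")
        # the printed form repeats DW(X) identically in both branches;
        # computing it once is mathematically the same
        shared = self.dw_in(x)
        a = self.act(self.expand_a(shared))
        b = self.act(self.expand_b(shared))
        out = self.reduce(a * b)
        out = self.bn(self.dw_out(out))
        if self.config.residual:
            out = out + x
        return out


class _StageConv(nn.Module):
    """3x3 conv + BN + ReLU6, stride 1."""

    def __init__(self, c_in, c_out, rng, dtype=np.float32):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 3, rng, padding=1, dtype=dtype)
        self.bn = nn.BatchNorm2d(c_out, dtype=dtype)

    def forward(self, x):
        return nn.relu6(self.bn(self.conv(x)))


class EncoderStage(nn.Module):
    def __init__(self, c_in: int, stage_index: int, config: EncoderConfig,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        width = config.stage_width(stage_index)
        star_cfg = StarBlockConfig(
            channels=width,
            expansion_factor=config.star.expansion_factor,
            dw_kernel=config.star.dw_kernel,
            activation=config.star.activation,
            residual=config.star.residual,
        )
        self.conv_in = _StageConv(c_in, width, rng, dtype)
        self.stars = nn.ModuleList(
            [StarBlock(star_cfg, rng, dtype)
             for _ in range(config.star_blocks_per_stage)])
        self.conv_out = _StageConv(width, width, rng, dtype)
        self.width = width

    def forward(self, x: Tensor):
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError(f"stage input {x.shape[2:]} not divisible by 2")
        y = self.conv_in(x)
        for star in self.stars:
            y = star(y)
        skip = self.conv_out(y)
        pooled = nn.maxpool2d(skip, 2)
        return skip, pooled


class Encoder(nn.Module):
    """Four stages with doubling widths plus a double-conv bottleneck at x16."""

    def __init__(self, c_in: int, config: EncoderConfig,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.config = config
        stages = []
        prev = c_in
        for i in range(1, 5):
            stage = EncoderStage(prev, i, config, rng, dtype)
            stages.append(stage)
            prev = stage.width
        self.stages = nn.ModuleList(stages)
        bottleneck_width = config.base_width * 16
        self.bottleneck = nn.Sequential(
            _StageConv(prev, bottleneck_width, rng, dtype),
            _StageConv(bottleneck_width, bottleneck_width, rng, dtype),
        )
        self.bottleneck_width = bottleneck_width

    def forward(self, x: Tensor):
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("encoder input spatial dims must be divisible by 16")
        skips = []
        y = x
        for stage in self.stages:
            skip, y = stage(y)
            skips.append(skip)
        return skips, self.bottleneck(y)
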