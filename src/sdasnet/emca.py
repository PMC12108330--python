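"""Feature-fusion branch: decoder stages with efficient multi-scale channel
attention (EMCA).

EMCA gates each channel of a decoder feature map using two descriptors: a
global one (global average pooling followed by a 1-D convolution across
channels) and a local one (grid average pooling, the same style of 1-D
convolution applied per grid cell).  The global map is broadcast-added to
the local map, squashed through a sigmoid, replicated back to the feature
map's spatial extent by nearest-neighbour un-pooling, and multiplied into
the feature map.  All learned weights are the two tiny 1-D kernels, so the
parameter count is independent of both spatial size and channel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class EMCAConfig:
    conv1d_kernel: int = 3
    local_grid: int = 4
    gate: str = "sigmoid"  # "sigmoid" | "linear" | "one" (constant-1, identity)

    def __post_init__(self):
        if self.conv1d_kernel % 2 == 0 or self.conv1d_kernel < 1:
            raise ValueError("conv1d_kernel must be odd and positive")
        if self.local_grid < 1:
            raise ValueError("local_grid must be >= 1")
        if self.gate not in ("sigmoid", "linear", "one"):
            raise ValueError(f"unknown gate {self.gate!r}")


class EMCA(nn.Module):
    def __init__(self, config: EMCAConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.config = config
        self.global_conv = nn.ChannelConv1d(config.conv1d_kernel, rng, dtype=dtype)
        self.local_conv = nn.ChannelConv1d(config.conv1d_kernel, rng, dtype=dtype)

    def forward(self, f: Tensor) -> Tensor:
        g = self.config.local_grid
        n, c, h, w = f.shape
        if h < g or w < g:
            raise ValueError(f"spatial dims {(h, w)} smaller than local grid {g}")
        if self.config.gate == "one":
            return f
        # global branch: GAP -> 1-D conv across channels
        gap = nn.mean(f, (2, 3))                      # (N, C)
        glob = self.global_conv(gap)                  # (N, C)
        glob = nn.reshape(glob, (n, c, 1, 1))
        # local branch: grid average pooling -> shared 1-D conv per cell
        lap = nn.adaptive_avgpool2d(f, (g, g))        # (N, C, g, g)
        loc = nn.transpose(lap, (0, 2, 3, 1))         # channels last
        loc = self.local_conv(loc)
        loc = nn.transpose(loc, (0, 3, 1, 2))
        # fuse, gate, un-pool, refine
        fused = loc + glob
        if self.config.gate == "sigmoid":
            fused = nn.sigmoid(fused)
        gate_map = nn.resize_nearest(fused, (h, w))
        return f * gate_map


class DecoderStage(nn.Module):
    """Upsample x2, concatenate the skip, double conv, then EMCA."""

    def __init__(self, deep_channels: int, skip_channels: int,
                 emca_config: EMCAConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.conv_a = nn.Conv2d(deep_channels + skip_channels, skip_channels,
                                3, rng, padding=1, dtype=dtype)
        self.bn_a = nn.BatchNorm2d(skip_channels, dtype=dtype)
        self.conv_b = nn.Conv2d(skip_channels, skip_channels, 3, rng,
                                padding=1, dtype=dtype)
        self.bn_b = nn.BatchNorm2d(skip_channels, dtype=dtype)
        self.emca = EMCA(emca_config, rng, dtype)
        self.skip_channels = skip_channels

    def forward(self, deep: Tensor, skip: Tensor) -> Tensor:
        up = nn.upsample_bilinear(deep, (skip.shape[2], skip.shape[3]))
        if up.shape[2] != skip.shape[2] or up.shape[3] != skip.shape[3]:
            raise ValueError("spatial mismatch between upsampled deep and skip")
        y = nn.concat([up, skip], axis=1)
        y = nn.relu6(self.bn_a(self.conv_a(y)))
        y = nn.relu6(self.bn_b(self.conv_b(y)))
        return self.emca(y)


class Decoder(nn.Module):
    """Four decoder stages consuming the refined skips deepest-first."""

    def __init__(self, bottleneck_channels: int, skip_channels: list[int],
                 emca_config: EMCAConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if len(skip_channels) != 4:
            raise ValueError("expected four skip widths")
        stages = []
        deep = bottleneck_channels
        for c_skip in reversed(skip_channels):
            stage = DecoderStage(deep, c_skip, emca_config, rng, dtype)
            stages.append(stage)
            deep = c_skip
        self.stages = nn.ModuleList(stages)

    def forward(self, bottleneck: Tensor, refined_skips: list[Tensor]) -> Tensor:
        y = bottleneck
        for stage, skip in zip(self.stages, reversed(refined_skips)):
            y = stage(y, skip)
        return y
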