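"""Wavelet-domain input-enhancement front end.

A two-branch module over the four sub-bands of the input image.  The
low-frequency branch widens the receptive field over the per-channel
approximation stack (1x1 conv, two 3x3 convs, a 3x3 dilated conv, each with
GELU).  The high-frequency branch projects the three detail stacks with 1x1
convs, concatenates them into a residual base, and runs four conv+GELU steps
each added back to that base.  The branch outputs are concatenated and passed
through a final 3x3 dilated convolution (optionally strided for
down-sampling) with batch normalisation and GELU.

The wavelet decomposition itself carries no learned weights; gradients flow
only into the convolutional branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .wavelet import WaveletFilters, dwt2_multichannel


@dataclass
class DWTModuleConfig:
    out_channels: int = 32
    mid_channels: int = 16
    dilation_rate: int = 2
    final_stride: int = 2
    input_channels: int = 3
    wavelet: str = "haar"

    def __post_init__(self):
        if min(self.out_channels, self.mid_channels, self.input_channels) < 1:
            raise ValueError("channel counts must be >= 1")
        if self.dilation_rate < 1:
            raise ValueError("dilation_rate must be >= 1")
        if self.final_stride not in (1, 2):
            raise ValueError("final_stride must be 1 or 2")


class DWTFrontEnd(nn.Module):
    def __init__(self, config: DWTModuleConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.config = config
        self.filters = WaveletFilters.from_family(config.wavelet)
        self.dtype = dtype
        c_in, mid, d = config.input_channels, config.mid_channels, config.dilation_rate
        # low-frequency branch over the cA stack
        self.low_1x1 = nn.Conv2d(c_in, mid, 1, rng, dtype=dtype)
        self.low_3x3_a = nn.Conv2d(mid, mid, 3, rng, padding=1, dtype=dtype)
        self.low_3x3_b = nn.Conv2d(mid, mid, 3, rng, padding=1, dtype=dtype)
        self.low_dil = nn.Conv2d(mid, mid, 3, rng, padding=d, dilation=d, dtype=dtype)
        # high-frequency branch: per-band 1x1 projections, then four
        # residual conv steps sharing the concatenated base
        self.high_1x1 = nn.ModuleList(
            [nn.Conv2d(c_in, mid, 1, rng, dtype=dtype) for _ in range(3)])
        self.high_steps = nn.ModuleList(
            [nn.Conv2d(3 * mid, 3 * mid, 3, rng, padding=1, dtype=dtype)
             for _ in range(4)])
        # fusion: dilated conv (down-sampling when final_stride=2) + BN + GELU
        self.fuse = nn.Conv2d(4 * mid, config.out_channels, 3, rng,
                              stride=config.final_stride, padding=d,
                              dilation=d, dtype=dtype)
        self.fuse_bn = nn.BatchNorm2d(config.out_channels, dtype=dtype)

    def decompose(self, batch: np.ndarray):
        """Per-channel single-level transform of (N, C, H, W) into
        (cA stack, [cH, cV, cD] stacks), numpy arrays outside the graph."""
        batch = np.asarray(batch)
        if batch.ndim != 4 or batch.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected (N, {self.config.input_channels}, H, W), got {batch.shape}")
        if batch.shape[2] % 2 or batch.shape[3] % 2:
            raise ValueError("spatial dims must be even for the decimated transform")
        c = self.config.input_channels
        cas, highs = [], []
        for sample in batch:
            ca, high = dwt2_multichannel(sample, self.filters)
            cas.append(ca)
            highs.append(high)
        ca = np.stack(cas).astype(self.dtype)
        high = np.stack(highs).astype(self.dtype)
        return ca, [high[:, i * c:(i + 1) * c] for i in range(3)]

    def forward(self, batch) -> Tensor:
        if isinstance(batch, Tensor):
            batch = batch.data
        ca, (i_lh, i_hl, i_hh) = self.decompose(batch)
        # low branch
        fl = nn.gelu(self.low_1x1(Tensor(ca)))
        fl = nn.gelu(self.low_3x3_a(fl))
        fl = nn.gelu(self.low_3x3_b(fl))
        fl = nn.gelu(self.low_dil(fl))
        # high branch
        projected = [conv(Tensor(band))
                     for conv, band in zip(self.high_1x1, (i_lh, i_hl, i_hh))]
        x1 = nn.concat(projected, axis=1)
        y = x1
        for step in self.high_steps:
            y = x1 + nn.gelu(step(y))
        fo = self.fuse(nn.concat([fl, y], axis=1))
        return nn.gelu(self.fuse_bn(fo))
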