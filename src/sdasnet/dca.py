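"""Dual cross-attention over the four encoder skips.

The four multi-scale skip features are average-pooled to a common G x G
token grid and projected with 1x1 depth-wise separable maps, giving four
token sequences with identical token count n_p = G^2 but stage-specific
channel widths.  Channel cross-attention (CCA) lets each stage's channels
attend over the channel-concatenated sequence of all stages; spatial
cross-attention (SCA) then lets token positions attend over positions using
queries/keys from the concatenated CCA output.  Both use residual
point-by-point summation; CCA is followed by batch normalisation + GELU and
the final DCA output by layer normalisation + GELU.  Refined token maps are
reshaped to G x G and bilinearly upsampled back to each skip's resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class DCAConfig:
    token_grid: int = 16
    heads: int = 1          # single-head; kept for extension
    norm_eps: float = 1e-6
    # test-harness switches (identity data path when all disabled)
    identity_attention: bool = False
    use_norm: bool = True
    use_residual: bool = True

    def __post_init__(self):
        if self.token_grid < 1:
            raise ValueError("token_grid must be >= 1")
        if self.heads != 1:
            raise ValueError("only single-head attention is implemented")


@dataclass
class TokenSequence:
    """Fixed-length token matrix of one encoder stage."""

    tokens: Tensor                 # (N, n_p, C_i)
    stage_index: int
    origin_shape: tuple            # (C_i, H_i, W_i)

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[1]

    @property
    def channels(self) -> int:
        return self.tokens.shape[2]


def flatten_tokens(fmap: Tensor) -> Tensor:
    """(N, C, G, G) -> (N, G*G, C), row-major token order."""
    n, c, g1, g2 = fmap.shape
    return nn.transpose(nn.reshape(fmap, (n, c, g1 * g2)), (0, 2, 1))


def unflatten_tokens(tokens: Tensor, grid: int) -> Tensor:
    """(N, n_p, C) -> (N, C, G, G)."""
    n, n_p, c = tokens.shape
    return nn.reshape(nn.transpose(tokens, (0, 2, 1)), (n, c, grid, grid))


class Tokenizer(nn.Module):
    """Average-pool one skip to the token grid and project per channel."""

    def __init__(self, channels: int, config: DCAConfig,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.config = config
        self.projection = nn.TokenProjection(channels, channels, rng, dtype=dtype)
        self.channels = channels

    def forward(self, fmap: Tensor, stage_index: int) -> TokenSequence:
        g = self.config.token_grid
        n, c, h, w = fmap.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        if h % g or w % g:
            raise ValueError(
                f"token grid {g} does not divide spatial dims {(h, w)}")
        pooled = nn.avgpool2d(fmap, h // g)
        tokens = self.projection(flatten_tokens(pooled))
        return TokenSequence(tokens, stage_index, (c, h, w))


class ChannelCrossAttention(nn.Module):
    """Per-stage queries attend over the channel-concatenated keys/values."""

    def __init__(self, stage_channels: list[int], config: DCAConfig,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.config = config
        cc = sum(stage_channels)
        self.norms = nn.ModuleList(
            [nn.LayerNorm(c, eps=config.norm_eps, dtype=dtype)
             for c in stage_channels])
        self.q_projs = nn.ModuleList(
            [nn.TokenProjection(c, c, rng, dtype=dtype) for c in stage_channels])
        self.k_proj = nn.TokenProjection(cc, cc, rng, dtype=dtype)
        self.v_proj = nn.TokenProjection(cc, cc, rng, dtype=dtype)
        self.out_projs = nn.ModuleList(
            [nn.TokenProjection(c, c, rng, dtype=dtype) for c in stage_channels])
        self.bns = nn.ModuleList(
            [nn.TokenBatchNorm(c, dtype=dtype) for c in stage_channels])
        self.scale = 1.0 / np.sqrt(cc)

    def attention_weights(self, q: Tensor, k: Tensor) -> Tensor:
        """softmax(Q^T K / sqrt(Cc)): (N, C_i, Cc), rows sum to one."""
        logits = nn.matmul(nn.transpose(q, (0, 2, 1)), k) * self.scale
        return nn.softmax(logits, axis=-1)

    def forward(self, sequences: list[TokenSequence]) -> list[TokenSequence]:
        n_p = {s.n_tokens for s in sequences}
        if len(n_p) != 1:
            raise ValueError(f"token counts differ across stages: {n_p}")
        cfg = self.config
        normed = [norm(s.tokens) if cfg.use_norm else s.tokens
                  for norm, s in zip(self.norms, sequences)]
        tc = nn.concat(normed, axis=-1)                       # (N, n_p, Cc)
        kc = self.k_proj(tc)
        vc = self.v_proj(tc)
        outputs = []
        for seq, normed_t, q_proj, out_proj, bn in zip(
                sequences, normed, self.q_projs, self.out_projs, self.bns):
            if cfg.identity_attention:
                attended = normed_t
            else:
                qi = q_proj(normed_t)
                attn = self.attention_weights(qi, kc)         # (N, C_i, Cc)
                out = nn.matmul(attn, nn.transpose(vc, (0, 2, 1)))  # (N, C_i, n_p)
                attended = nn.transpose(out, (0, 2, 1))
            y = out_proj(attended)
            if cfg.use_residual:
                y = y + seq.tokens
            if cfg.use_norm:
                y = nn.gelu(bn(y))
            outputs.append(TokenSequence(y, seq.stage_index, seq.origin_shape))
        return outputs


class SpatialCrossAttention(nn.Module):
    """Token positions attend over positions; queries/keys come from the
    channel-concatenated CCA output, values are per-stage."""

    def __init__(self, stage_channels: list[int], config: DCAConfig,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.config = config
        cc = sum(stage_channels)
        self.q_proj = nn.TokenProjection(cc, cc, rng, dtype=dtype)
        self.k_proj = nn.TokenProjection(cc, cc, rng, dtype=dtype)
        self.norms = nn.ModuleList(
            [nn.LayerNorm(c, eps=config.norm_eps, dtype=dtype)
             for c in stage_channels])
        self.v_projs = nn.ModuleList(
            [nn.TokenProjection(c, c, rng, dtype=dtype) for c in stage_channels])
        self.out_projs = nn.ModuleList(
            [nn.TokenProjection(c, c, rng, dtype=dtype) for c in stage_channels])
        self.out_norms = nn.ModuleList(
            [nn.LayerNorm(c, eps=config.norm_eps, dtype=dtype)
             for c in stage_channels])
        self.scale = 1.0 / np.sqrt(cc)  # d_k = key projection channel count

    def attention_weights(self, q: Tensor, k: Tensor) -> Tensor:
        """softmax(Q K^T / sqrt(d_k)): (N, n_p, n_p), rows sum to one."""
        logits = nn.matmul(q, nn.transpose(k, (0, 2, 1))) * self.scale
        return nn.softmax(logits, axis=-1)

    def forward(self, sequences: list[TokenSequence]) -> list[TokenSequence]:
        cfg = self.config
        tcc = nn.concat([s.tokens for s in sequences], axis=-1)
        qs = self.q_proj(tcc)
        ks = self.k_proj(tcc)
        attn = None if cfg.identity_attention else self.attention_weights(qs, ks)
        outputs = []
        for seq, norm, v_proj, out_proj, out_norm in zip(
                sequences, self.norms, self.v_projs, self.out_projs,
                self.out_norms):
            vi = v_proj(norm(seq.tokens) if cfg.use_norm else seq.tokens)
            attended = vi if attn is None else nn.matmul(attn, vi)
            y = out_proj(attended)
            if cfg.use_residual:
                y = y + seq.tokens
            if cfg.use_norm:
                y = nn.gelu(out_norm(y))
            outputs.append(TokenSequence(y, seq.stage_index, seq.origin_shape))
        return outputs


class DCA(nn.Module):
    """Tokenize the four skips, run CCA then SCA, re-project to feature maps."""

    def __init__(self, stage_channels: list[int], config: DCAConfig,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if len(stage_channels) != 4:
            raise ValueError("expected four encoder stages")
        self.config = config
        self.tokenizers = nn.ModuleList(
            [Tokenizer(c, config, rng, dtype) for c in stage_channels])
        self.cca = ChannelCrossAttention(stage_channels, config, rng, dtype)
        self.sca = SpatialCrossAttention(stage_channels, config, rng, dtype)

    def tokenize(self, skips: list[Tensor]) -> list[TokenSequence]:
        return [tok(skip, i + 1)
                for i, (tok, skip) in enumerate(zip(self.tokenizers, skips))]

    def forward(self, skips: list[Tensor]) -> list[Tensor]:
        sequences = self.tokenize(skips)
        sequences = self.cca(sequences)
        sequences = self.sca(sequences)
        g = self.config.token_grid
        refined = []
        for seq in sequences:
            fmap = unflatten_tokens(seq.tokens, g)
            _, h, w = seq.origin_shape
            refined.append(nn.upsample_bilinear(fmap, (h, w)))
        return refined
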