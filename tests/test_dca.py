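import numpy as np
import pytest

import sdasnet.nn as nn
from sdasnet import (DCA, ChannelCrossAttention, DCAConfig,
                     SpatialCrossAttention, Tokenizer, TokenSequence)
from sdasnet.dca import flatten_tokens, unflatten_tokens
from sdasnet.nn import Tensor

from _oracles import patch_mean_bruteforce


def set_identity(proj):
    """Make a TokenProjection the identity map."""
    proj.dw_weight.data[...] = 1.0
    proj.pw_weight.data[...] = np.eye(*proj.pw_weight.shape)
    proj.bias.data[...] = 0.0
    return proj


def walk_modules(module):
    yield module
    for child in module._modules.values():
        yield from walk_modules(child)


def raw_config(**kwargs):
    """Attention arithmetic only: no normalisation, no residual."""
    return DCAConfig(use_norm=False, use_residual=False, **kwargs)


def cca_oracle(t):
    """Hand evaluation of channel cross-attention with identity projections.

    t: (n_p, C) single-stage token matrix; Q = K = V = t.
    logits[i, j] = sum_p t[p, i] t[p, j] / sqrt(C);
    out[p, i] = sum_j softmax(logits)[i, j] t[p, j].
    """
    n_p, c = t.shape
    logits = np.zeros((c, c))
    for i in range(c):
        for j in range(c):
            logits[i, j] = sum(t[p, i] * t[p, j] for p in range(n_p))
    logits /= np.sqrt(c)
    attn = np.exp(logits - logits.max(axis=1, keepdims=True))
    attn /= attn.sum(axis=1, keepdims=True)
    out = np.zeros((n_p, c))
    for p in range(n_p):
        for i in range(c):
            out[p, i] = sum(attn[i, j] * t[p, j] for j in range(c))
    return out


class TestTokenizer:
    def test_token_shape(self, rng):
        tok = Tokenizer(8, DCAConfig(token_grid=8), np.random.default_rng(0))
        seq = tok(Tensor(rng.random((1, 8, 32, 32)).astype(np.float32)), 1)
        assert seq.tokens.shape == (1, 64, 8)
        assert seq.n_tokens == 64 and seq.channels == 8
        assert seq.origin_shape == (8, 32, 32)

    def test_constant_map_gives_constant_tokens(self):
        tok = Tokenizer(4, DCAConfig(token_grid=4), np.random.default_rng(1))
        set_identity(tok.projection)
        seq = tok(Tensor(np.full((1, 4, 16, 16), 2.5, dtype=np.float32)), 1)
        np.testing.assert_allclose(seq.tokens.data, 2.5, atol=1e-6)

    def test_pooled_tokens_match_patch_mean_oracle(self, rng):
        g = 4
        tok = Tokenizer(3, DCAConfig(token_grid=g), np.random.default_rng(2))
        set_identity(tok.projection)
        fmap = rng.random((1, 3, 16, 16)).astype(np.float32)
        seq = tok(Tensor(fmap), 1)
        want = patch_mean_bruteforce(fmap[0], g)          # (C, g, g)
        got = seq.tokens.data[0].reshape(g, g, 3).transpose(2, 0, 1)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_grid_must_divide_spatial_dims(self, rng):
        tok = Tokenizer(8, DCAConfig(token_grid=4), np.random.default_rng(3))
        with pytest.raises(ValueError):
            tok(Tensor(rng.random((1, 8, 10, 10))), 1)

    def test_channel_mismatch_rejected(self, rng):
        tok = Tokenizer(8, DCAConfig(token_grid=2), np.random.default_rng(4))
        with pytest.raises(ValueError):
            tok(Tensor(rng.random((1, 4, 8, 8))), 1)


def test_flatten_unflatten_roundtrip(rng):
    fmap = Tensor(rng.random((2, 5, 4, 4)).astype(np.float32))
    back = unflatten_tokens(flatten_tokens(fmap), 4)
    np.testing.assert_array_equal(back.data, fmap.data)


class TestChannelCrossAttention:
    def test_attention_rows_sum_to_one(self, rng):
        cca = ChannelCrossAttention([2, 3], DCAConfig(token_grid=2),
                                    np.random.default_rng(0))
        q = Tensor(rng.normal(size=(1, 4, 2)).astype(np.float32))
        k = Tensor(rng.normal(size=(1, 4, 5)).astype(np.float32))
        w = cca.attention_weights(q, k).data
        assert w.shape == (1, 2, 5)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(w >= 0)

    def test_two_token_two_channel_hand_example(self):
        # expected values frozen from the hand-evaluated oracle
        cca = ChannelCrossAttention([2], raw_config(token_grid=2),
                                    np.random.default_rng(1))
        for p in (cca.q_projs[0], cca.k_proj, cca.v_proj, cca.out_projs[0]):
            set_identity(p)
        t = np.array([[1.0, 0.0], [0.0, 2.0]])
        seq = TokenSequence(Tensor(t[None].astype(np.float32)), 1, (2, 4, 4))
        out = cca([seq])[0].tokens.data[0]
        np.testing.assert_allclose(out, cca_oracle(t), atol=1e-6)

    def test_random_tokens_match_oracle(self, rng):
        cca = ChannelCrossAttention([3], raw_config(token_grid=2),
                                    np.random.default_rng(2))
        for p in (cca.q_projs[0], cca.k_proj, cca.v_proj, cca.out_projs[0]):
            set_identity(p)
        t = rng.normal(size=(4, 3))
        seq = TokenSequence(Tensor(t[None].astype(np.float32)), 1, (3, 4, 4))
        out = cca([seq])[0].tokens.data[0]
        np.testing.assert_allclose(out, cca_oracle(t), atol=1e-5)

    def test_token_count_mismatch_rejected(self, rng):
        cca = ChannelCrossAttention([2, 2], DCAConfig(token_grid=2),
                                    np.random.default_rng(3))
        a = TokenSequence(Tensor(rng.random((1, 4, 2))), 1, (2, 4, 4))
        b = TokenSequence(Tensor(rng.random((1, 9, 2))), 2, (2, 6, 6))
        with pytest.raises(ValueError):
            cca([a, b])


class TestSpatialCrossAttention:
    def test_attention_rows_sum_to_one(self, rng):
        sca = SpatialCrossAttention([2, 2], DCAConfig(token_grid=2),
                                    np.random.default_rng(0))
        q = Tensor(rng.normal(size=(1, 4, 4)).astype(np.float32))
        k = Tensor(rng.normal(size=(1, 4, 4)).astype(np.float32))
        w = sca.attention_weights(q, k).data
        assert w.shape == (1, 4, 4)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_uniform_logits_give_row_means_of_values(self, rng):
        """Zeroed query projection -> uniform attention -> every output token
        is the mean over tokens of that stage's value sequence."""
        widths = [2, 3, 2, 1]
        sca = SpatialCrossAttention(widths, raw_config(token_grid=2),
                                    np.random.default_rng(1))
        sca.q_proj.dw_weight.data[...] = 0.0
        sca.q_proj.pw_weight.data[...] = 0.0
        sca.q_proj.bias.data[...] = 0.0
        for v, o in zip(sca.v_projs, sca.out_projs):
            set_identity(v)
            set_identity(o)
        seqs = [TokenSequence(
            Tensor(rng.normal(size=(1, 4, c)).astype(np.float32)), i + 1,
            (c, 4, 4)) for i, c in enumerate(widths)]
        outs = sca(seqs)
        for seq, out in zip(seqs, outs):
            want = seq.tokens.data.mean(axis=1, keepdims=True)
            np.testing.assert_allclose(out.tokens.data,
                                       np.broadcast_to(want, out.tokens.shape),
                                       atol=1e-6)

    def test_permutation_equivariance(self, rng):
        widths = [2, 3]
        sca = SpatialCrossAttention(widths, DCAConfig(token_grid=2),
                                    np.random.default_rng(2))
        seqs = [TokenSequence(
            Tensor(rng.normal(size=(1, 4, c)).astype(np.float32)), i + 1,
            (c, 4, 4)) for i, c in enumerate(widths)]
        perm = np.array([2, 0, 3, 1])
        permuted = [TokenSequence(Tensor(s.tokens.data[:, perm]),
                                  s.stage_index, s.origin_shape) for s in seqs]
        base = sca(seqs)
        shuffled = sca(permuted)
        for b, s in zip(base, shuffled):
            np.testing.assert_allclose(s.tokens.data, b.tokens.data[:, perm],
                                       atol=1e-5)


class TestDCA:
    WIDTHS = [4, 8, 16, 32]
    SIZES = [32, 16, 8, 4]

    def make_skips(self, rng, requires_grad=False):
        return [Tensor(rng.random((1, c, s, s)).astype(np.float32),
                       requires_grad=requires_grad)
                for c, s in zip(self.WIDTHS, self.SIZES)]

    def test_refined_skips_keep_shapes(self, rng):
        dca = DCA(self.WIDTHS, DCAConfig(token_grid=4),
                  np.random.default_rng(0))
        refined = dca(self.make_skips(rng))
        assert [r.shape for r in refined] == \
            [(1, c, s, s) for c, s in zip(self.WIDTHS, self.SIZES)]

    def test_identity_path_reduces_to_pool_then_upsample(self, rng):
        cfg = raw_config(token_grid=4, identity_attention=True)
        dca = DCA(self.WIDTHS, cfg, np.random.default_rng(1))
        for m in walk_modules(dca):
            if isinstance(m, nn.TokenProjection):
                set_identity(m)
        skips = self.make_skips(rng)
        refined = dca(skips)
        for skip, r, s in zip(skips, refined, self.SIZES):
            pooled = nn.avgpool2d(skip, s // 4)
            want = nn.upsample_bilinear(pooled, (s, s)).data
            np.testing.assert_allclose(r.data, want, atol=1e-5)

    def test_gradients_reach_all_skips_and_parameters(self, rng):
        dca = DCA(self.WIDTHS, DCAConfig(token_grid=4),
                  np.random.default_rng(2))
        skips = self.make_skips(rng, requires_grad=True)
        loss = None
        for r in dca(skips):
            term = nn.sum_(r * r)
            loss = term if loss is None else loss + term
        loss.backward()
        for i, s in enumerate(skips):
            assert s.grad is not None and np.any(s.grad != 0), f"skip {i}"
        for name, p in dca.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name

    def test_requires_four_stages(self):
        with pytest.raises(ValueError):
            DCA([4, 8], DCAConfig(token_grid=2), np.random.default_rng(3))

    def test_deterministic(self, rng):
        dca = DCA(self.WIDTHS, DCAConfig(token_grid=4),
                  np.random.default_rng(4)).eval()
        skips = self.make_skips(rng)
        a = [r.data for r in dca(skips)]
        b = [r.data for r in dca(skips)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
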