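"""Spatial-prior adapter: convolutional pyramid, injector, extractor, decoder.

A small convolutional stem (the Spatial Prior Module, SPM) downsamples the
input image to a 1/8, 1/16, 1/32 feature pyramid, which is flattened into a
multi-scale token sequence.  At each of N interaction rounds, the *injector*
adds gated cross-attention from these spatial tokens into the ViT stream
(query = ViT tokens), and the *extractor* refines the spatial tokens by
cross-attending to the ViT output of the round followed by a convolutional
feed-forward network (CFFN) with a per-scale 3x3 depthwise convolution.
The injector gate gamma_i is initialized to exactly zero, so at
initialization the ViT stream is bit-for-bit independent of the SPM branch.
"""

from __future__ import annotations

import numpy as np

from .nn import functional as F
from .nn.modules import (Conv2d, LayerNorm, Linear, Module,
                         MultiHeadAttention)
from .nn.tensor import Parameter, Tensor
from .vit import TokenSequence

__all__ = ["SpatialPriorModule", "Injector", "Extractor", "CFFN",
           "PixelDecoder", "spm_token_count"]


def spm_token_count(h: int, w: int) -> int:
    """Tokens emitted by the SPM pyramid: hw/64 + hw/256 + hw/1024."""
    return (h * w) // 64 + (h * w) // 256 + (h * w) // 1024


def _maps_to_tokens(x, gh: int, gw: int):
    # (B, C, gh, gw) -> (B, gh*gw, C)
    b, c = x.shape[0], x.shape[1]
    return x.reshape((b, c, gh * gw)).transpose(0, 2, 1)


def _tokens_to_maps(x, gh: int, gw: int):
    b, c = x.shape[0], x.shape[-1]
    return x.transpose(0, 2, 1).reshape((b, c, gh, gw))


class _ConvStage(Module):
    """conv3x3(stride 2) -> channel LayerNorm -> ReLU."""

    def __init__(self, c_in, c_out, rng):
        self.conv = Conv2d(c_in, c_out, 3, rng, stride=2, padding=1)
        self.norm = LayerNorm(c_out)

    def forward(self, x):
        x = self.conv(x)
        b, c, h, w = x.shape
        t = self.norm(x.reshape((b, c, h * w)).transpose(0, 2, 1))
        return F.relu(t).transpose(0, 2, 1).reshape((b, c, h, w))


class SpatialPriorModule(Module):
    """Convolutional stem producing the 1/8-1/16-1/32 token pyramid.

    Three stride-2 stages reach 1/8 resolution, two further stride-2 stages
    give 1/16 and 1/32; each scale is tapped through a 1x1 projection to
    ``width`` channels before flattening (scale-major concatenation).
    """

    def __init__(self, width: int, rng: np.random.Generator,
                 stem_channels: int | None = None):
        ch = stem_channels or max(8, width // 4)
        self.width = width
        self.stage1 = _ConvStage(3, ch, rng)
        self.stage2 = _ConvStage(ch, ch * 2, rng)
        self.stage3 = _ConvStage(ch * 2, ch * 4, rng)          # 1/8
        self.stage4 = _ConvStage(ch * 4, ch * 4, rng)          # 1/16
        self.stage5 = _ConvStage(ch * 4, ch * 4, rng)          # 1/32
        self.proj1 = Conv2d(ch * 4, width, 1, rng)
        self.proj2 = Conv2d(ch * 4, width, 1, rng)
        self.proj3 = Conv2d(ch * 4, width, 1, rng)

    def forward(self, images) -> TokenSequence:
        images = np.asarray(images, dtype=np.float64)
        b, h, w, _ = images.shape
        if h % 32 or w % 32:
            raise ValueError(f"image size {h}x{w} not divisible by 32")
        x = Tensor(images.transpose(0, 3, 1, 2))
        x8 = self.stage3(self.stage2(self.stage1(x)))
        x16 = self.stage4(x8)
        x32 = self.stage5(x16)
        f1, f2, f3 = self.proj1(x8), self.proj2(x16), self.proj3(x32)
        grids = [(h // 8, w // 8), (h // 16, w // 16), (h // 32, w // 32)]
        tokens = F.concat([_maps_to_tokens(f, gh, gw)
                           for f, (gh, gw) in zip((f1, f2, f3), grids)], axis=1)
        return TokenSequence(tokens, grids)


class Injector(Module):
    """ViT <- spatial cross-attention with a zero-initialized scalar gate."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.ln_q = LayerNorm(dim)
        self.ln_kv = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.gamma = Parameter(np.zeros(()))

    def forward(self, seq: TokenSequence, fsp: TokenSequence) -> TokenSequence:
        if seq.tokens.shape[-1] != fsp.tokens.shape[-1]:
            raise ValueError("token width mismatch between ViT and SPM branch")
        att = self.attn(self.ln_q(seq.tokens), self.ln_kv(fsp.tokens))
        return TokenSequence(seq.tokens + self.gamma * att, seq.grids,
                             has_class_token=seq.has_class_token)


class CFFN(Module):
    """Feed-forward with a per-scale 3x3 depthwise convolution.

    Linear down-projection to ``hidden``, per-scale reshape to maps and a
    shared depthwise conv, GELU, linear up-projection.  The residual is the
    caller's business.
    """

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.dw = Conv2d(hidden, hidden, 3, rng, padding=1, groups=hidden)
        self.fc2 = Linear(hidden, dim, rng, std=0.02)

    def forward(self, x, seq: TokenSequence):
        if not seq.grids:
            raise ValueError("CFFN needs per-scale grid metadata")
        h = self.fc1(x)
        pieces = []
        for (lo, hi), (gh, gw) in zip(seq.scale_slices(), seq.grids):
            m = _tokens_to_maps(h[:, lo:hi, :], gh, gw)
            pieces.append(_maps_to_tokens(self.dw(m), gh, gw))
        h = F.concat(pieces, axis=1)
        return self.fc2(F.gelu(h))


class Extractor(Module):
    """Spatial <- ViT cross-attention followed by the CFFN (both residual)."""

    def __init__(self, dim: int, heads: int, cffn_hidden: int,
                 rng: np.random.Generator):
        self.ln_q = LayerNorm(dim)
        self.ln_kv = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.ln_ffn = LayerNorm(dim)
        self.cffn = CFFN(dim, cffn_hidden, rng)

    def forward(self, fsp: TokenSequence, seq: TokenSequence) -> TokenSequence:
        att = self.attn(self.ln_q(fsp.tokens), self.ln_kv(seq.tokens))
        fhat = TokenSequence(fsp.tokens + att, fsp.grids)
        out = fhat.tokens + self.cffn(self.ln_ffn(fhat.tokens), fhat)
        return TokenSequence(out, fsp.grids)


class PixelDecoder(Module):
    """Extracted pyramid -> dense per-pixel embedding map ``f(X)``.

    Per-scale tokens are reshaped to maps, the 1/16 and 1/32 maps are
    bilinearly upsampled to 1/8 and summed, a 1x1 convolution projects to the
    embedding dimension ``n``, and the result is bilinearly upsampled to the
    full image resolution.  Output layout (B, H, W, n).
    """

    def __init__(self, dim: int, n: int, rng: np.random.Generator):
        # small init keeps pre-lift feature norms O(0.1): the exponential-map
        # lift is gradient-responsive near the origin and saturates near the
        # ball shell, so embeddings must start small and grow as needed
        self.proj = Conv2d(dim, n, 1, rng, init_std=0.02)
        self.n = n

    def forward(self, fsp: TokenSequence, out_h: int, out_w: int):
        maps = []
        for (lo, hi), (gh, gw) in zip(fsp.scale_slices(), fsp.grids):
            maps.append(_tokens_to_maps(fsp.tokens[:, lo:hi, :], gh, gw))
        gh0, gw0 = fsp.grids[0]
        acc = maps[0]
        for m in maps[1:]:
            acc = acc + F.bilinear_resize(m, gh0, gw0)
        emb = F.bilinear_resize(self.proj(acc), out_h, out_w)
        return emb.transpose(0, 2, 3, 1)
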