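"""Plain Vision Transformer encoder with grouped blocks.

The encoder is the standard pre-norm ViT: non-overlapping patch embedding
plus learned positional embeddings, then ``depth`` blocks of multi-head
self-attention and an MLP, each wrapped in LayerNorm-first residuals.  For
segmentation no class token is used by default, keeping a bijection between
tokens and patch cells; the blocks are partitioned into ``interactions``
equal groups so an adapter can interact with the token stream between
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import functional as F
from .nn.modules import LayerNorm, Linear, Mlp, Module, MultiHeadAttention
from .nn.tensor import Parameter, Tensor

__all__ = ["TokenSequence", "EncoderBlock", "ViTBackbone"]


@dataclass
class TokenSequence:
    """Flattened tokens plus the spatial grid(s) they came from.

    ``grids`` records one ``(gh, gw)`` pair per scale; the token count must
    equal the summed grid areas (plus one if a class token is prepended).
    """

    tokens: Tensor
    grids: list = field(default_factory=list)
    has_class_token: bool = False

    def __post_init__(self):
        t = self.tokens.shape[-2]
        expect = sum(gh * gw for gh, gw in self.grids) + int(self.has_class_token)
        if t != expect:
            raise ValueError(f"token count {t} does not match grids {self.grids}")

    @property
    def num_tokens(self) -> int:
        return self.tokens.shape[-2]

    def scale_slices(self):
        """Per-scale index ranges into the token axis (class token excluded)."""
        out, start = [], int(self.has_class_token)
        for gh, gw in self.grids:
            out.append((start, start + gh * gw))
            start += gh * gw
        return out


class EncoderBlock(Module):
    def __init__(self, dim: int, heads: int, ffn: int,
                 rng: np.random.Generator, out_std: float = 0.02):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng, out_std=out_std)
        self.ln2 = LayerNorm(dim)
        self.mlp = Mlp(dim, ffn, rng, out_std=out_std)

    def forward(self, x):
        h = self.ln1(x)
        x = x + self.attn(h, h)
        x = x + self.mlp(self.ln2(x))
        return x


class ViTBackbone(Module):
    """Patch embedding + positional embeddings + grouped encoder blocks.

    Parameters
    ----------
    patch, width, depth, heads, ffn : int
        Standard ViT hyperparameters (full-size defaults elsewhere:
        patch 16, width 768, depth 12, heads 12, FFN 3072).
    interactions : int
        Number of equal block groups N; ``depth`` must be divisible by it.
    ref_grid : (int, int)
        Grid the positional embeddings are sized for; other input sizes get
        bilinearly interpolated positions.
    class_token : bool
        Prepend a class token (discarded after the encoder).  Off by
        default: segmentation needs the token/patch bijection only.
    """

    def __init__(self, *, patch: int, width: int, depth: int, heads: int,
                 ffn: int, interactions: int, ref_grid=(16, 16),
                 class_token: bool = False, rng: np.random.Generator):
        if depth % interactions:
            raise ValueError("depth must be divisible by interactions")
        self.patch = patch
        self.width = width
        self.depth = depth
        self.interactions = interactions
        self.ref_grid = tuple(ref_grid)
        self.class_token = bool(class_token)
        # residual output projections scaled down with depth for stability
        out_std = 0.02 / np.sqrt(2.0 * depth)
        self.embed = Linear(patch * patch * 3, width, rng)
        self.pos = Parameter(rng.normal(
            0.0, 0.02, (self.ref_grid[0] * self.ref_grid[1], width)))
        if self.class_token:
            self.cls = Parameter(np.zeros((1, width)))
        self.blocks = [EncoderBlock(width, heads, ffn, rng, out_std=out_std)
                       for _ in range(depth)]

    # ------------------------------------------------------------------ ops
    def _pos_for(self, gh: int, gw: int):
        rh, rw = self.ref_grid
        if (gh, gw) == (rh, rw):
            return self.pos
        grid = self.pos.reshape((rh, rw, self.width)).transpose(2, 0, 1)
        grid = F.bilinear_resize(grid.reshape((1, self.width, rh, rw)), gh, gw)
        return grid.reshape((self.width, gh * gw)).transpose(1, 0)

    def patchify(self, images: np.ndarray) -> TokenSequence:
        """(B, H, W, 3) float image batch -> embedded token sequence."""
        images = np.asarray(images, dtype=np.float64)
        b, h, w, _ = images.shape
        p = self.patch
        if h % p or w % p:
            raise ValueError(f"image size {h}x{w} not divisible by patch {p}")
        gh, gw = h // p, w // p
        x = images.reshape(b, gh, p, gw, p, 3)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, gh * gw, p * p * 3)
        tokens = self.embed(Tensor(x)) + self._pos_for(gh, gw)
        if self.class_token:
            cls = F.stack([self.cls * 1.0] * b, axis=0)
            tokens = F.concat([cls, tokens], axis=1)
        return TokenSequence(tokens, [(gh, gw)],
                             has_class_token=self.class_token)

    def run_block_group(self, seq: TokenSequence, group_index: int) -> TokenSequence:
        n = self.interactions
        if not 0 <= group_index < n:
            raise IndexError(f"group index {group_index} out of range 0..{n - 1}")
        per = self.depth // n
        x = seq.tokens
        for blk in self.blocks[group_index * per:(group_index + 1) * per]:
            x = blk(x)
        return TokenSequence(x, seq.grids, has_class_token=seq.has_class_token)

    def forward(self, images) -> TokenSequence:
        seq = self.patchify(images)
        for i in range(self.interactions):
            seq = self.run_block_group(seq, i)
        return seq
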