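"""The full segmentation model: ViT + spatial-prior adapter + hyperbolic head.

``HyperbolicSegModel.forward`` maps an image batch (B, H, W, 3) to per-pixel
class logits (B, H, W, C).  Interaction schedule per round i of N:

    inject   : b_i   <- b_i + gamma_i * Attn(LN(b_i), LN(F_i_sp))
    backbone : b_i+1 <- encoder group i (b_i)
    extract  : F_i+1_sp <- residual cross-attention + CFFN from b_i+1

after which the extracted pyramid is decoded to dense pixel embeddings and
classified by the gyroplane bank.  ``baseline=True`` swaps the adapter for
the ablation variant: a size-preserving transposed-convolution refinement of
the token grid between encoder groups and a transposed-convolution decoder.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .adapter import Extractor, Injector, PixelDecoder, SpatialPriorModule
from .head import GyroplaneBank, hyperbolic_logits
from .nn import functional as F
from .nn.modules import ConvTranspose2d, Module
from .vit import TokenSequence, ViTBackbone

__all__ = ["ModelConfig", "HyperbolicSegModel", "CLASS_NAMES", "CLASS_INDEX"]

# class 0 is background; lesion order fixed package-wide
CLASS_NAMES = ("background", "EX", "HE", "MA", "SE")
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass
class ModelConfig:
    """All architecture hyperparameters (full-size defaults).

    ``adapter_width`` defaults to the ViT width; the cross-attention requires
    matched widths, and a 1x1 projection inside the SPM realizes it.
    """

    image_size: int = 512
    patch: int = 16
    width: int = 768
    depth: int = 12
    heads: int = 12
    ffn: int = 3072
    interactions: int = 4
    adapter_width: int | None = None
    adapter_heads: int = 12
    cffn_hidden: int = 96
    cffn_ratio: float = 0.25
    embed_dim: int = 64
    num_classes: int = 5
    curvature: float = 1.0
    max_feature_norm: float | None = 3.0
    negate_offset: bool = True
    class_token: bool = False
    baseline: bool = False
    multilabel: bool = False

    def resolved_adapter_width(self) -> int:
        return self.adapter_width if self.adapter_width else self.width

    def to_dict(self) -> dict:
        return asdict(self)


class HyperbolicSegModel(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        if cfg.width != cfg.resolved_adapter_width() and not cfg.baseline:
            raise ValueError(
                "adapter_width must equal the ViT width for cross-attention; "
                "set adapter_width=None to inherit it")
        self.cfg = cfg
        g = cfg.image_size // cfg.patch
        self.backbone = ViTBackbone(
            patch=cfg.patch, width=cfg.width, depth=cfg.depth, heads=cfg.heads,
            ffn=cfg.ffn, interactions=cfg.interactions, ref_grid=(g, g),
            class_token=cfg.class_token, rng=rng)
        n_inter = cfg.interactions
        if cfg.baseline:
            # token-grid refinement between groups, size preserving
            self.refine = [ConvTranspose2d(cfg.width, cfg.width, 3, rng,
                                           stride=1, padding=1)
                           for _ in range(n_inter)]
            self.deconv = ConvTranspose2d(cfg.width, cfg.embed_dim, 4, rng,
                                          stride=2, padding=1)
        else:
            aw = cfg.resolved_adapter_width()
            self.spm = SpatialPriorModule(aw, rng)
            self.injectors = [Injector(aw, cfg.adapter_heads, rng)
                              for _ in range(n_inter)]
            self.extractors = [Extractor(aw, cfg.adapter_heads,
                                         cfg.cffn_hidden, rng)
                               for _ in range(n_inter)]
            self.decoder = PixelDecoder(aw, cfg.embed_dim, rng)
        if cfg.multilabel:
            self.banks = [GyroplaneBank(2, cfg.embed_dim, cfg.curvature, rng,
                                        negate_offset=cfg.negate_offset,
                                        max_feature_norm=cfg.max_feature_norm)
                          for _ in CLASS_NAMES[1:]]
        else:
            self.bank = GyroplaneBank(cfg.num_classes, cfg.embed_dim,
                                      cfg.curvature, rng,
                                      negate_offset=cfg.negate_offset,
                                      max_feature_norm=cfg.max_feature_norm)

    # ------------------------------------------------------------------ api
    def manifold_parameters(self):
        banks = self.banks if self.cfg.multilabel else [self.bank]
        out = []
        for b in banks:
            out += [p for _, p in b.named_parameters()]
        return out

    def euclidean_parameters(self):
        manifold = {id(p) for p in self.manifold_parameters()}
        return [p for _, p in self.named_parameters() if id(p) not in manifold]

    def pixel_embeddings(self, images, *, disable_injection: bool = False,
                         stream_log: list | None = None):
        """Dense Euclidean features f(X): (B, H, W, n)."""
        images = np.asarray(images, dtype=np.float64)
        images = (images - 0.5) * 2.0       # [0,1] -> [-1,1]
        b, h, w, _ = images.shape
        seq = self.backbone.patchify(images)
        if self.cfg.baseline:
            gh, gw = seq.grids[0]
            for i in range(self.cfg.interactions):
                seq = self.backbone.run_block_group(seq, i)
                if stream_log is not None:
                    stream_log.append(seq.tokens.data.copy())
                if i < self.cfg.interactions - 1:
                    x = seq.tokens.transpose(0, 2, 1).reshape(
                        (b, self.cfg.width, gh, gw))
                    x = self.refine[i](x)
                    toks = x.reshape((b, self.cfg.width, gh * gw)).transpose(0, 2, 1)
                    seq = TokenSequence(toks, seq.grids)
            x = seq.tokens.transpose(0, 2, 1).reshape((b, self.cfg.width, gh, gw))
            emb = F.bilinear_resize(self.deconv(x), h, w)
            return emb.transpose(0, 2, 3, 1)
        fsp = self.spm(images)
        for i in range(self.cfg.interactions):
            if not disable_injection:
                seq = self.injectors[i](seq, fsp)
            seq = self.backbone.run_block_group(seq, i)
            if stream_log is not None:
                stream_log.append(seq.tokens.data.copy())
            fsp = self.extractors[i](fsp, seq)
        return self.decoder(fsp, h, w)

    def forward(self, images, **kw):
        emb = self.pixel_embeddings(images, **kw)
        if self.cfg.multilabel:
            return F.stack([hyperbolic_logits(emb, b) for b in self.banks],
                           axis=-2)                    # (B, H, W, 4, 2)
        return self.bank(emb)                          # (B, H, W, C)

    def predict_proba(self, images) -> np.ndarray:
        """Per-pixel class probabilities, numpy, no graph."""
        logits = self.forward(images)
        out = F.softmax(logits.data if hasattr(logits, "data") else logits,
                        axis=-1)
        return out
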