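"""scikit-learn style estimator facade.

``HyperbolicLesionSegmenter`` wraps model construction, the SGD/RSGD
training loop and prediction behind the familiar ``fit`` / ``predict`` /
``predict_proba`` surface, so the segmenter composes with sklearn pipelines
and model-selection utilities.  ``X`` is an array of RGB images
``(N, H, W, 3)`` with values in [0, 1] and ``H = W`` divisible by 32; ``y``
is an integer label-map array ``(N, H, W)`` (0 background, 1 EX, 2 HE,
3 MA, 4 SE) or a list of per-class binary mask dicts.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import SegmentationSample
from .model import CLASS_NAMES, HyperbolicSegModel, ModelConfig
from .pipeline import TrainConfig, evaluate, train

__all__ = ["HyperbolicLesionSegmenter"]


def _to_samples(X, y):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError("X must have shape (N, H, W, 3)")
    samples = []
    for i in range(X.shape[0]):
        if y is None:
            samples.append(SegmentationSample(X[i]))
            continue
        yi = y[i]
        if isinstance(yi, dict):
            samples.append(SegmentationSample(X[i], dict(yi)))
        else:
            yi = np.asarray(yi)
            masks = {}
            for k, name in enumerate(CLASS_NAMES[1:], start=1):
                m = (yi == k).astype(np.uint8)
                if m.any():
                    masks[name] = m
            samples.append(SegmentationSample(X[i], masks))
    return samples


class HyperbolicLesionSegmenter(BaseEstimator):
    """Hyperbolic-head ViT-adapter segmenter with an sklearn interface.

    Parameters mirror the model and training configuration; see
    :class:`hyperseg.model.ModelConfig` and
    :class:`hyperseg.pipeline.TrainConfig`.  ``curvature=0`` selects the
    exact Euclidean degenerate branch of the classification head.
    """

    def __init__(self, *, image_size=128, patch=16, width=64, depth=4,
                 heads=2, ffn=128, interactions=2, adapter_heads=2,
                 cffn_hidden=16, embed_dim=16, curvature=1.0,
                 max_feature_norm=3.0, negate_offset=True, baseline=False,
                 multilabel=False, lr0=4e-3, momentum=0.9, poly_power=0.9,
                 epochs=75, batch=4, max_steps=None, optimizer="adam",
                 head_lr_scale=20.0, grad_clip=5.0, head_grad_clip=0.0,
                 warmup=0, seed=17):
        self.image_size = image_size
        self.patch = patch
        self.width = width
        self.depth = depth
        self.heads = heads
        self.ffn = ffn
        self.interactions = interactions
        self.adapter_heads = adapter_heads
        self.cffn_hidden = cffn_hidden
        self.embed_dim = embed_dim
        self.curvature = curvature
        self.max_feature_norm = max_feature_norm
        self.negate_offset = negate_offset
        self.baseline = baseline
        self.multilabel = multilabel
        self.lr0 = lr0
        self.momentum = momentum
        self.poly_power = poly_power
        self.epochs = epochs
        self.batch = batch
        self.max_steps = max_steps
        self.optimizer = optimizer
        self.head_lr_scale = head_lr_scale
        self.grad_clip = grad_clip
        self.head_grad_clip = head_grad_clip
        self.warmup = warmup
        self.seed = seed

    # ------------------------------------------------------------------
    def _configs(self):
        mcfg = ModelConfig(
            image_size=self.image_size, patch=self.patch, width=self.width,
            depth=self.depth, heads=self.heads, ffn=self.ffn,
            interactions=self.interactions, adapter_heads=self.adapter_heads,
            cffn_hidden=self.cffn_hidden, embed_dim=self.embed_dim,
            curvature=self.curvature, max_feature_norm=self.max_feature_norm,
            negate_offset=self.negate_offset,
            baseline=self.baseline, multilabel=self.multilabel)
        tcfg = TrainConfig(
            lr0=self.lr0, momentum=self.momentum, poly_power=self.poly_power,
            epochs=self.epochs, batch=self.batch, max_steps=self.max_steps,
            optimizer=self.optimizer, head_lr_scale=self.head_lr_scale,
            grad_clip=self.grad_clip, head_grad_clip=self.head_grad_clip,
            warmup=self.warmup, seed=self.seed,
            image_size=self.image_size)
        return mcfg, tcfg

    def fit(self, X, y):
        samples = _to_samples(X, y)
        mcfg, tcfg = self._configs()
        self.model_ = HyperbolicSegModel(mcfg, np.random.default_rng(self.seed))
        self.history_ = train(self.model_, samples, tcfg)
        self.classes_ = np.arange(mcfg.num_classes)
        self.n_features_in_ = int(np.prod(np.asarray(X).shape[1:]))
        return self

    def predict_proba(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        return np.stack([self.model_.predict_proba(X[i:i + 1])[0]
                         for i in range(X.shape[0])])

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=-1)

    def score(self, X, y):
        """Mean pixel accuracy against integer label maps."""
        y = np.asarray(y)
        return float((self.predict(X) == y).mean())

    def evaluate_auc(self, X, y):
        """Per-lesion pooled AUC_PR/AUC_ROC dict (sklearn-free surface)."""
        self._check_fitted()
        return evaluate(self.model_, _to_samples(X, y))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
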