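"""Training, evaluation, prediction and checkpointing.

The optimizer is split exactly along the parameter geometry: Euclidean
parameters (backbone, adapter, decoder) take SGD with momentum, the
gyroplane bank's manifold parameters take Riemannian SGD; both follow the
same polynomial learning-rate decay ``lr0 * (1 - step/max_steps)^power``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import head as H
from .data import IGNORE_INDEX, LESION_CLASSES, resize_sample
from .metrics import binary_auc
from .model import CLASS_INDEX, HyperbolicSegModel, ModelConfig
from .nn import SGD, clip_grad_norm
from .nn.optim import Adam

__all__ = ["TrainConfig", "poly_lr", "train", "evaluate", "predict",
           "save_checkpoint", "load_checkpoint"]

log = logging.getLogger("hyperseg")


@dataclass
class TrainConfig:
    lr0: float = 0.001
    momentum: float = 0.9
    poly_power: float = 0.9
    epochs: int = 100
    batch: int = 2
    max_steps: int | None = None       # overrides epochs when set
    optimizer: str = "sgd"             # Euclidean side: "sgd" or "adam"
    head_lr_scale: float = 1.0         # RSGD lr multiplier for the bank
    grad_clip: float = 5.0             # Euclidean global grad-norm clip
    head_grad_clip: float = 0.0        # optional separate clip for the bank
    warmup: int = 0                    # linear warmup steps before poly decay
    seed: int = 17
    image_size: int = 512

    def __post_init__(self):
        if self.lr0 <= 0 or self.poly_power <= 0:
            raise ValueError("lr0 and poly_power must be positive")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


def poly_lr(step: int, max_steps: int, cfg: TrainConfig) -> float:
    """``lr0 * (1 - step/max_steps)^poly_power``."""
    if not 0 <= step <= max_steps:
        raise ValueError("step outside schedule range")
    return cfg.lr0 * (1.0 - step / max_steps) ** cfg.poly_power


def _sample_arrays(samples, size: int):
    images, labels, mask_stack = [], [], []
    for s in samples:
        s = resize_sample(s, size)
        images.append(s.image)
        labels.append(s.label_map)
        mask_stack.append(np.stack(
            [s.masks.get(c, np.zeros((size, size), np.uint8))
             for c in LESION_CLASSES]))
    return np.stack(images), np.stack(labels), np.stack(mask_stack)


def _batch_loss(model: HyperbolicSegModel, images, labels, masks):
    logits = model(images)
    if model.cfg.multilabel:
        total = 0.0
        for k in range(len(LESION_CLASSES)):
            total = total + H.segmentation_loss(
                logits[:, :, :, k, :], (masks[:, k] > 0).astype(np.int64))
        return total * (1.0 / len(LESION_CLASSES))
    return H.segmentation_loss(logits, labels, IGNORE_INDEX)


def train(model: HyperbolicSegModel, samples, cfg: TrainConfig,
          callback=None) -> list:
    """Run the optimization loop; returns the per-step history.

    Each history row records step, loss, lr and the injector gate values.
    Aborts with a diagnostic on a non-finite loss.
    """
    rng = np.random.default_rng(cfg.seed)
    images, labels, masks = _sample_arrays(samples, cfg.image_size)
    n = len(samples)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch)))
    max_steps = cfg.max_steps or cfg.epochs * steps_per_epoch
    if cfg.optimizer == "adam":
        opt_euc = Adam(model.euclidean_parameters())
    else:
        opt_euc = SGD(model.euclidean_parameters(), momentum=cfg.momentum)
    banks = model.banks if model.cfg.multilabel else [model.bank]
    opt_rie = [H.RiemannianSGD(b) for b in banks]
    history, step = [], 0
    while step < max_steps:
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch):
            if step >= max_steps:
                break
            idx = order[lo:lo + cfg.batch]
            loss = _batch_loss(model, images[idx], labels[idx], masks[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at step {step}, batch {idx.tolist()}")
            for p in model.parameters():
                p.zero_grad()
            loss.backward()
            # clip the two parameter families separately: a joint norm lets
            # the large Euclidean tensors rescale (and silently slow) the
            # few-hundred-parameter bank
            if cfg.grad_clip:
                clip_grad_norm(model.euclidean_parameters(), cfg.grad_clip)
            if cfg.head_grad_clip:
                for b in banks:
                    clip_grad_norm([p for _, p in b.named_parameters()],
                                   cfg.head_grad_clip)
            lr = poly_lr(step, max_steps, cfg)
            if cfg.warmup:
                lr *= min(1.0, (step + 1) / cfg.warmup)
            opt_euc.step(lr)
            for o in opt_rie:
                o.step(lr * cfg.head_lr_scale)
            gammas = [float(i.gamma.data) for i in model.injectors] \
                if not model.cfg.baseline else []
            row = {"step": step, "loss": float(loss.data), "lr": lr,
                   "gammas": gammas}
            history.append(row)
            if callback:
                callback(row)
            if step % 25 == 0:
                log.info("step %d loss %.4f lr %.2e", step,
                         row["loss"], lr)
            step += 1
    return history


def _lesion_score_maps(model: HyperbolicSegModel, image) -> dict:
    proba = model.predict_proba(image[None])[0]
    if model.cfg.multilabel:
        return {c: proba[:, :, k, 1] for k, c in enumerate(LESION_CLASSES)}
    return {c: proba[:, :, CLASS_INDEX[c]] for c in LESION_CLASSES}


def evaluate(model: HyperbolicSegModel, samples, size: int | None = None):
    """Per-lesion AUC_PR / AUC_ROC over pooled pixels of the split.

    Classes absent from a sample's annotations contribute no pixels for that
    class; a class with no positives anywhere is reported as ``None``.
    """
    if not samples:
        raise ValueError("empty evaluation split")
    size = size or model.cfg.image_size
    pooled = {c: ([], []) for c in LESION_CLASSES}
    for s in samples:
        s = resize_sample(s, size)
        score_maps = _lesion_score_maps(model, s.image)
        for c in LESION_CLASSES:
            if c in s.masks:
                pooled[c][0].append(score_maps[c].ravel())
                pooled[c][1].append(s.masks[c].ravel())
    results = {}
    for c, (scores, labels) in pooled.items():
        if not scores:
            results[c] = None
            continue
        results[c] = binary_auc(np.concatenate(scores),
                                np.concatenate(labels), class_name=c)
    return results


def metrics_to_json(results: dict, model: HyperbolicSegModel) -> dict:
    out = {"curvature": model.cfg.curvature, "classes": {}}
    for c, r in results.items():
        out["classes"][c] = None if r is None else r.to_dict()
    present = [r for r in results.values() if r is not None]
    if present:
        out["mean_auc_pr"] = float(np.mean([r.auc_pr for r in present]))
        out["mean_auc_roc"] = float(np.mean([r.auc_roc for r in present]))
    return out


def predict(model: HyperbolicSegModel, image, outdir=None):
    """Score maps + argmax label map for one image; optional PNG dump."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    if h % 32 or w % 32:
        raise ValueError(f"image size {h}x{w} must be divisible by 32")
    proba = model.predict_proba(image[None])[0]
    if model.cfg.multilabel:
        lesion = np.stack([proba[:, :, k, 1]
                           for k in range(len(LESION_CLASSES))], axis=-1)
        bg = np.clip(1.0 - lesion.max(axis=-1), 0, 1)[..., None]
        full = np.concatenate([bg, lesion], axis=-1)
    else:
        full = proba
    label = full.argmax(axis=-1).astype(np.uint8)
    if outdir is not None:
        from PIL import Image as PILImage
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = ("background",) + LESION_CLASSES
        for k, name in enumerate(names[:full.shape[-1]]):
            PILImage.fromarray(
                (full[:, :, k] * 255).round().astype(np.uint8)).save(
                outdir / f"prob_{name}.png")
        pal = PILImage.fromarray(label, mode="P")
        pal.putpalette([0, 0, 0, 255, 255, 0, 180, 30, 30,
                        255, 80, 80, 240, 240, 200] + [0] * (256 * 3 - 15))
        pal.save(outdir / "labels.png")
    return full, label


# ------------------------------------------------------------- checkpoints
def save_checkpoint(path, model: HyperbolicSegModel, train_cfg: TrainConfig,
                    history=None):
    """Weights + model/train config + seed in a single ``.npz``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"model": model.cfg.to_dict(), "train": asdict(train_cfg),
            "seed": train_cfg.seed, "final_loss":
                history[-1]["loss"] if history else None}
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    """Returns ``(model, train_cfg, meta)`` reconstructed from disk."""
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    mcfg = ModelConfig(**meta["model"])
    tcfg = TrainConfig(**meta["train"])
    model = HyperbolicSegModel(mcfg, np.random.default_rng(meta["seed"]))
    model.load_state_dict(state)
    return model, tcfg, meta
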