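"""Deterministic synthetic fundus-like data.

Real fundus photographs with pixel-level lesion annotation are large and
externally hosted; this module emulates their *structure* so the whole
pipeline is exercisable offline: a dark field with a reddish radial-gradient
disc and low-frequency noise stands in for the retina, and four lesion
archetypes are placed programmatically —

* ``EX``  bright, sharp-edged yellowish blobs (hard exudates),
* ``HE``  dark reddish blobs (haemorrhages),
* ``MA``  dots of a few pixels (microaneurysms; radii capped at 3 px),
* ``SE``  diffuse, heavily blurred pale patches (soft exudates).

Masks record the pre-blur supports.  Every sample is reproducible from its
seed; a fixture *set* derives one counter-based stream per sample from
``(global seed, sample index)`` so samples are independent of generation
order.  These images carry none of the photometric complexity of real
fundus data (vessels, illumination artefacts, camera noise) — tests passing
on them demonstrate mechanics and trainability, not clinical performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .data import LESION_CLASSES, SegmentationSample

__all__ = ["LesionSpec", "default_specs", "generate_sample",
           "make_fixture_set", "write_layout", "tiny_config"]

# additive RGB direction per class; multiplied by the signed intensity
_TINTS = {
    "EX": np.array([1.00, 0.92, 0.45]),
    "HE": np.array([0.55, 1.00, 0.90]),   # negative intensity -> dark red
    "MA": np.array([0.50, 1.00, 0.90]),
    "SE": np.array([0.95, 0.95, 0.80]),
}


@dataclass
class LesionSpec:
    """Placement recipe for one lesion class."""

    name: str
    count: tuple            # inclusive (lo, hi) number of lesions
    radius: tuple           # (lo, hi) radius in pixels
    intensity: float        # signed additive offset (positive = brighter)
    softness: float         # Gaussian blur sigma applied to the profile

    def __post_init__(self):
        if self.name not in LESION_CLASSES:
            raise ValueError(f"unknown class {self.name!r}")
        if self.name == "MA" and self.radius[1] > 3:
            raise ValueError("microaneurysm radii must stay <= 3 px")
        if self.name == "EX" and self.intensity <= 0:
            raise ValueError("EX intensity offset must be positive")
        if self.name == "HE" and self.intensity >= 0:
            raise ValueError("HE intensity offset must be negative")


def default_specs() -> list:
    """Study-condition defaults; SE is softer than EX by construction."""
    return [
        LesionSpec("EX", (3, 8), (4.0, 10.0), +0.45, 0.6),
        LesionSpec("HE", (2, 6), (5.0, 12.0), -0.35, 0.8),
        LesionSpec("MA", (8, 20), (1.0, 2.0), -0.30, 0.3),
        LesionSpec("SE", (1, 4), (8.0, 16.0), +0.25, 3.0),
    ]


def _background(rng: np.random.Generator, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx) / (0.48 * size)
    disc = np.clip(1.0 - r ** 2, 0.0, 1.0)
    base = np.stack([0.10 + 0.38 * disc, 0.06 + 0.22 * disc,
                     0.04 + 0.10 * disc], axis=-1)
    coarse = rng.normal(0.0, 1.0, (8, 8, 3))
    noise = np.stack([np.asarray(Image.fromarray(
        coarse[..., k].astype(np.float32), mode="F").resize(
        (size, size), Image.BILINEAR), dtype=np.float64)
        for k in range(3)], axis=-1)
    return base + 0.02 * noise


def _place(rng: np.random.Generator, size: int, spec: LesionSpec,
           center=None):
    """One lesion: (pre-blur binary support, blurred additive profile)."""
    r = rng.uniform(*spec.radius)
    margin = max(4.0, r + 2)
    if center is None:
        ang = rng.uniform(0, 2 * np.pi)
        rad = 0.40 * size * np.sqrt(rng.uniform(0.02, 1.0))
        cy = size / 2 + rad * np.sin(ang)
        cx = size / 2 + rad * np.cos(ang)
        cy = float(np.clip(cy, margin, size - margin))
        cx = float(np.clip(cx, margin, size - margin))
    else:
        cy, cx = center
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(yy - cy, xx - cx)
    support = (dist <= r).astype(np.uint8)
    profile = np.clip(1.0 - (dist / r) ** 2, 0.0, 1.0)
    profile = gaussian_filter(profile, spec.softness)
    return support, profile, (cy, cx)


def generate_sample(seed: int, size: int = 256, specs=None, *,
                    force_overlap: bool = False) -> SegmentationSample:
    """Draw one synthetic fundus image with masks, reproducible from seed."""
    if size % 32:
        raise ValueError("size must be divisible by 32")
    rng = np.random.default_rng(seed)
    specs = default_specs() if specs is None else specs
    img = _background(rng, size)
    masks = {s.name: np.zeros((size, size), dtype=np.uint8) for s in specs}
    first_center = None
    for spec in specs:
        n = int(rng.integers(spec.count[0], spec.count[1] + 1))
        for _ in range(n):
            support, profile, center = _place(rng, size, spec)
            if first_center is None and spec.name != "MA":
                first_center = center
            masks[spec.name] |= support
            img += spec.intensity * _TINTS[spec.name] * profile[..., None]
    if force_overlap and first_center is not None:
        ma = next((s for s in specs if s.name == "MA"), None)
        if ma is not None:
            support, profile, _ = _place(rng, size, ma, center=first_center)
            masks["MA"] |= support
            img += ma.intensity * _TINTS["MA"] * profile[..., None]
    img = np.clip(img, 0.0, 1.0)
    masks = {k: v for k, v in masks.items() if v.any()}
    return SegmentationSample(img, masks, name=f"synth_{seed:06d}")


def make_fixture_set(seed: int = 17, n: int = 8, size: int = 256,
                     specs=None) -> list:
    """Standard fixture set; sample 0 carries a guaranteed class overlap."""
    return [generate_sample(
        int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31)),
        size, specs, force_overlap=(i == 0))
        for i in range(n)]


def write_layout(samples, root, layout: str = "idrid", *,
                 force: bool = False) -> dict:
    """Write samples to disk in the named folder convention.

    idrid/synthetic get train/test splits (2:1); ddr gets train/valid/test
    (2:1:1).  Images are PNG, masks one-bit TIFF per class.  Returns a
    manifest dict, also written to ``root/manifest.json``.
    """
    import tifffile

    root = Path(root)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(f"{root} exists and is not empty (use force)")
    if layout == "ddr":
        bounds = [(0, len(samples) // 2, "train"),
                  (len(samples) // 2, 3 * len(samples) // 4, "valid"),
                  (3 * len(samples) // 4, len(samples), "test")]
    elif layout in ("idrid", "synthetic"):
        cut = max(1, 2 * len(samples) // 3)
        bounds = [(0, cut, "train"), (cut, len(samples), "test")]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    manifest = {"layout": layout, "splits": {}}
    for lo, hi, split in bounds:
        entries = []
        for s in samples[lo:hi]:
            img_dir = root / split / "images"
            img_dir.mkdir(parents=True, exist_ok=True)
            img_path = img_dir / f"{s.name}.png"
            Image.fromarray((s.image * 255).round().astype(np.uint8)).save(img_path)
            for cls, m in s.masks.items():
                mdir = root / split / "masks" / cls
                mdir.mkdir(parents=True, exist_ok=True)
                tifffile.imwrite(mdir / f"{s.name}.tif",
                                 (m * 255).astype(np.uint8))
            entries.append({"name": s.name, "classes": sorted(s.masks)})
        manifest["splits"][split] = entries
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def tiny_config() -> dict:
    """A full pipeline configuration that trains in minutes on one CPU."""
    return {
        "model": {
            "image_size": 128, "patch": 16, "width": 64, "depth": 4,
            "heads": 2, "ffn": 128, "interactions": 2,
            "adapter_width": 64, "adapter_heads": 2, "cffn_hidden": 16,
            "embed_dim": 16, "num_classes": 5, "curvature": 1.0,
        },
        "train": {
            "lr0": 4e-3, "momentum": 0.9, "poly_power": 0.9,
            "batch": 4, "epochs": 150, "max_steps": 300,
            "optimizer": "adam", "head_lr_scale": 20.0,
            "grad_clip": 5.0, "head_grad_clip": 0.0, "seed": 17,
        },
        "data": {"size": 128, "layout": "synthetic"},
    }
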