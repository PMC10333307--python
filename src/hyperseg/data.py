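"""Dataset containers and readers for IDRiD/DDR-style folder layouts.

A segmentation sample is a fundus RGB image plus up to four binary lesion
masks keyed ``EX`` (hard exudates), ``HE`` (haemorrhages), ``MA``
(microaneurysms) and ``SE`` (soft exudates); an absent key means the image
carries no annotation for that class.  Overlapping masks are resolved into a
single label map by the fixed priority MA > SE > HE > EX — the rarest and
smallest lesion wins a contested pixel.

Folder conventions (images PNG/JPEG, masks TIFF or PNG):

    idrid / synthetic:  root/{train,test}/images/*            ddr adds valid/
                        root/{train,test}/masks/<CLS>/<stem>.tif
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .model import CLASS_INDEX

__all__ = ["SegmentationSample", "load_dataset", "resize_sample",
           "LESION_CLASSES", "PRIORITY", "IGNORE_INDEX", "label_map_from_masks"]

LESION_CLASSES = ("EX", "HE", "MA", "SE")
#: paint order; later entries overwrite earlier ones on overlap
PRIORITY = ("EX", "HE", "SE", "MA")
IGNORE_INDEX = 255

log = logging.getLogger("hyperseg")

_IMG_EXT = (".png", ".jpg", ".jpeg")
_MASK_EXT = (".tif", ".tiff", ".png")


def label_map_from_masks(masks: dict, shape) -> np.ndarray:
    """Binary per-class masks -> integer label map (0 = background)."""
    lab = np.zeros(shape, dtype=np.int64)
    for cls in PRIORITY:
        if cls in masks:
            lab[np.asarray(masks[cls]) > 0] = CLASS_INDEX[cls]
    return lab


@dataclass
class SegmentationSample:
    image: np.ndarray                    # (H, W, 3) float64 in [0, 1]
    masks: dict = field(default_factory=dict)   # class -> (H, W) uint8 {0,1}
    name: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        for cls, m in self.masks.items():
            if cls not in LESION_CLASSES:
                raise ValueError(f"unknown lesion class {cls!r}")
            m = (np.asarray(m) > 0).astype(np.uint8)
            if m.shape != self.image.shape[:2]:
                raise ValueError(f"mask {cls} shape {m.shape} does not match "
                                 f"image {self.image.shape[:2]}")
            self.masks[cls] = m

    @property
    def label_map(self) -> np.ndarray:
        return label_map_from_masks(self.masks, self.image.shape[:2])


def _read_image(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    except Exception as exc:                      # noqa: BLE001
        raise IOError(f"unreadable image file: {path}") from exc
    return arr / 255.0


def _read_mask(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile
            arr = np.asarray(tifffile.imread(path))
        else:
            with Image.open(path) as im:
                arr = np.asarray(im.convert("L"))
    except Exception as exc:                      # noqa: BLE001
        raise IOError(f"unreadable mask file: {path}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > (arr.max() / 2 if arr.max() > 1 else 0)).astype(np.uint8)


def _splits_for(layout: str):
    if layout in ("idrid", "synthetic"):
        return ("train", "test")
    if layout == "ddr":
        return ("train", "valid", "test")
    raise ValueError(f"unknown layout {layout!r}; expected idrid, ddr or synthetic")


def load_dataset(root, layout: str = "idrid", split: str = "train"):
    """Read one split of a dataset in the named layout.

    Returns samples in deterministic (lexicographic) order.  Missing
    per-class mask files yield absent keys and are counted in the log.
    """
    root = Path(root)
    if split not in _splits_for(layout):
        raise ValueError(f"layout {layout!r} has no split {split!r}")
    img_dir = root / split / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no image directory at {img_dir}")
    files = sorted(p for p in img_dir.iterdir()
                   if p.suffix.lower() in _IMG_EXT)
    if not files:
        raise ValueError(f"empty dataset split: {img_dir}")
    samples, missing = [], {cls: 0 for cls in LESION_CLASSES}
    for path in files:
        masks = {}
        for cls in LESION_CLASSES:
            found = None
            for ext in _MASK_EXT:
                cand = root / split / "masks" / cls / (path.stem + ext)
                if cand.exists():
                    found = cand
                    break
            if found is None:
                missing[cls] += 1
            else:
                masks[cls] = _read_mask(found)
        samples.append(SegmentationSample(_read_image(path), masks,
                                          name=path.stem))
    log.info("loaded %d samples from %s (%s/%s); missing masks: %s",
             len(samples), root, layout, split,
             {k: v for k, v in missing.items() if v})
    return samples


def resize_sample(sample: SegmentationSample, size: int) -> SegmentationSample:
    """Bilinear image / nearest-neighbour mask resize to ``size x size``."""
    if sample.image.shape[:2] == (size, size):
        return sample
    im = Image.fromarray((sample.image * 255).astype(np.uint8))
    im = im.resize((size, size), Image.BILINEAR)
    masks = {}
    for cls, m in sample.masks.items():
        mm = Image.fromarray(m * 255).resize((size, size), Image.NEAREST)
        masks[cls] = (np.asarray(mm) > 127).astype(np.uint8)
    return SegmentationSample(np.asarray(im, dtype=np.float64) / 255.0,
                              masks, name=sample.name)
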