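"""YAML configuration: sections ``model``, ``train``, ``data``.

Defaults carry the published full-size settings (patch 16, width 768,
FFN 3072, 12 heads, N=4 interactions, CFFN hidden 96 at ratio 1/4, adapter
12 heads, lr 0.001, momentum 0.9, poly power 0.9, batch 2, curvature 1.0);
a user file overrides any subset.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .pipeline import TrainConfig

__all__ = ["default_config", "load_config", "build_configs"]


def default_config() -> dict:
    return {
        "model": {f.name: getattr(ModelConfig(), f.name)
                  for f in fields(ModelConfig)},
        "train": {f.name: getattr(TrainConfig(), f.name)
                  for f in fields(TrainConfig)},
        "data": {"size": 512, "layout": "idrid"},
    }


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            if section not in cfg:
                raise KeyError(f"unknown config section {section!r}")
            unknown = set(values) - set(cfg[section])
            if unknown:
                raise KeyError(f"unknown keys in [{section}]: {sorted(unknown)}")
            cfg[section].update(values)
    return cfg


def build_configs(cfg: dict):
    """Config dict -> (ModelConfig, TrainConfig)."""
    mcfg = ModelConfig(**cfg.get("model", {}))
    tr = dict(cfg.get("train", {}))
    tr.setdefault("image_size", mcfg.image_size)
    tcfg = TrainConfig(**tr)
    tcfg.image_size = mcfg.image_size
    return mcfg, tcfg
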