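"""YAML run configuration: backbone / neck / detector / data blocks.

A run config is a plain nested mapping; :func:`load_config` merges a YAML
file with dotted-path command-line overrides and resolves it into a
:class:`~maizedet.detector.DetectorConfig`.  Every CLI run serialises the
resolved config next to its outputs so results are reproducible from the
run folder alone.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .detector import DetectorConfig
from .pyramid import PyramidConfig

__all__ = ["load_config", "resolve_detector_config", "save_config",
           "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "classes": [],
    "backbone": {
        "depth": "tiny",
        "deformable": True,
        "deformable_stages": ["C3", "C4", "C5"],
        "pretrained": False,
    },
    "neck": {
        "channels": 32,
        "attention": True,
        "attention_channels": 1,
        "literal_subsample_variant": False,
    },
    "detector": {
        "levels": ["P2", "P3", "P4", "P5", "P6"],
        "anchor_scales": [4.0, 5.7],
        "anchor_ratios": [1.0],
        "max_proposals": 50,
        "roi_pool_size": 4,
        "roi_hidden": 128,
        "rois_per_image": 64,
        "canonical_scale": 32.0,
        "canonical_level": 3,
        "score_thresh": 0.05,
        "nms_thresh": 0.5,
    },
    "train": {
        "epochs": 5,
        "lr": 0.01,
        "momentum": 0.9,
    },
}


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def _apply_override(cfg: dict, dotted: str, value: str) -> None:
    keys = dotted.split(".")
    node = cfg
    for k in keys[:-1]:
        node = node.setdefault(k, {})
    node[keys[-1]] = yaml.safe_load(value)


def load_config(path=None, overrides: list[str] | None = None) -> dict:
    """Defaults <- YAML file <- ``key.path=value`` overrides, in that order."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _deep_update(cfg, loaded)
    for ov in overrides or []:
        if "=" not in ov:
            raise ValueError(f"override {ov!r} must look like key.path=value")
        key, val = ov.split("=", 1)
        _apply_override(cfg, key, val)
    return cfg


def resolve_detector_config(cfg: dict) -> DetectorConfig:
    seed = int(cfg.get("seed", 0))
    bb = cfg.get("backbone", {})
    nk = cfg.get("neck", {})
    dt = cfg.get("detector", {})
    tr = cfg.get("train", {})
    classes = tuple(cfg.get("classes", []))
    if not classes:
        raise ValueError("config must list at least one class under 'classes'")
    backbone = BackboneConfig(
        depth=bb.get("depth", "tiny"),
        deformable=bool(bb.get("deformable", True)),
        deformable_stages=tuple(bb.get("deformable_stages", ("C3", "C4", "C5"))),
        seed=seed,
    )
    pyramid = PyramidConfig(
        channels=int(nk.get("channels", 32)),
        attention=bool(nk.get("attention", True)),
        attention_channels=int(nk.get("attention_channels", 1)),
        literal_subsample_variant=bool(nk.get("literal_subsample_variant", False)),
        hidden_channels=nk.get("hidden_channels"),
        seed=seed + 1,
    )
    return DetectorConfig(
        class_names=classes,
        backbone=backbone,
        pyramid=pyramid,
        levels=tuple(dt.get("levels", ("P2", "P3", "P4", "P5", "P6"))),
        anchor_scales=tuple(dt.get("anchor_scales", (4.0, 5.7))),
        anchor_ratios=tuple(dt.get("anchor_ratios", (1.0,))),
        max_proposals=int(dt.get("max_proposals", 50)),
        roi_pool_size=int(dt.get("roi_pool_size", 4)),
        roi_hidden=int(dt.get("roi_hidden", 128)),
        rois_per_image=int(dt.get("rois_per_image", 64)),
        canonical_scale=float(dt.get("canonical_scale", 32.0)),
        canonical_level=int(dt.get("canonical_level", 3)),
        score_thresh=float(dt.get("score_thresh", 0.05)),
        nms_thresh=float(dt.get("nms_thresh", 0.5)),
        lr=float(tr.get("lr", 0.01)),
        momentum=float(tr.get("momentum", 0.9)),
        epochs=int(tr.get("epochs", 5)),
        seed=seed,
    )


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
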