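"""Seeded generator of pest-like synthetic scenes with VOC annotations.

The generator does not attempt biological realism: pests are procedurally
drawn superellipse blobs with class-keyed colour and shape signatures on a
textured background.  What it *does* emulate, because the detector has to
cope with it, is the statistical structure of a field corn-pest dataset:
bounding-box sizes spanning two orders of magnitude relative to the image
(0.007-0.306 in area), a strongly imbalanced class mixture, and controlled
occlusion/density regimes.  Every rendered object carries a tight bounding
box recomputed from its rasterised mask, so annotations are exactly
consistent with pixel geometry (within one pixel of rasterisation).

Relative sizes are sampled log-uniformly in *area* terms, matching the
area-ratio definition used by :func:`maizedet.voc.relative_size`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .examples import PEST_CLASSES, TABLE1_INSTANCE_COUNTS, TABLE1_RELATIVE_SIZES
from .metrics import Box
from .voc import AnnotationRecord, dataset_stats, write_voc_xml

__all__ = [
    "ClassSpec",
    "SceneConfig",
    "generate_scene",
    "generate_records",
    "generate_dataset",
    "preset",
    "PRESETS",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassSpec:
    """Rendering signature of one synthetic pest class."""

    name: str
    color: tuple[float, float, float]          # mean RGB in [0,1]
    rel_area: tuple[float, float]              # log-uniform box-area ratio range
    aspect: tuple[float, float] = (0.7, 1.4)   # width/height ratio range
    squareness: tuple[float, float] = (1.6, 3.0)  # superellipse exponent

    @property
    def mean_rel_area(self) -> float:
        """Analytic mean of the log-uniform area-ratio distribution."""
        lo, hi = self.rel_area
        if hi == lo:
            return lo
        return (hi - lo) / np.log(hi / lo)


@dataclass(frozen=True)
class SceneConfig:
    image_size: tuple[int, int] = (64, 64)     # (H, W)
    classes: tuple[ClassSpec, ...] = ()
    mixture_weights: tuple[float, ...] = ()    # per-class; sums to 1
    instances_per_image: tuple[int, int] = (1, 2)  # inclusive range
    occlusion_prob: float = 0.0
    max_overlap: float = 0.3                   # IoU cap for occluding pairs
    texture_level: float = 0.15                # background clutter in [0,1]
    seed: int = 0
    max_place_tries: int = 40

    def __post_init__(self):
        if self.classes:
            w = np.asarray(self.mixture_weights, dtype=float)
            if len(w) != len(self.classes):
                raise ValueError("one mixture weight per class required")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must sum to 1, got {w.sum()}")
        for c in self.classes:
            lo, hi = c.rel_area
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError(
                    f"class {c.name}: rel_area range must lie in (0,1)")


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    H, W = cfg.image_size
    base = np.array([0.28, 0.38, 0.18])  # muted foliage green
    img = np.broadcast_to(base, (H, W, 3)).copy()
    if cfg.texture_level > 0:
        # low-frequency blotches: coarse noise upsampled by replication
        coarse = rng.normal(0.0, 1.0, size=(max(2, H // 8), max(2, W // 8), 3))
        up = np.kron(coarse, np.ones((8, 8, 1)))[:H, :W]
        img += 0.25 * cfg.texture_level * up
        img += 0.12 * cfg.texture_level * rng.normal(0.0, 1.0, size=(H, W, 3))
    return np.clip(img, 0.0, 1.0)


def _draw_blob(img: np.ndarray, cls: ClassSpec, cx: float, cy: float,
               a: float, b: float, theta: float, exponent: float,
               rng: np.random.Generator) -> Box | None:
    """Rasterise one superellipse; returns the tight box of drawn pixels."""
    H, W = img.shape[:2]
    ys, xs = np.mgrid[0:H, 0:W]
    u = (xs + 0.5 - cx) * np.cos(theta) + (ys + 0.5 - cy) * np.sin(theta)
    v = -(xs + 0.5 - cx) * np.sin(theta) + (ys + 0.5 - cy) * np.cos(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        mask = (np.abs(u / a) ** exponent + np.abs(v / b) ** exponent) <= 1.0
    if not mask.any():
        return None
    color = np.clip(np.asarray(cls.color) + rng.normal(0, 0.04, 3), 0, 1)
    speckle = 1.0 + 0.25 * rng.normal(0.0, 1.0, size=(H, W, 1))
    img[mask] = np.clip(color * speckle[mask], 0.0, 1.0)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return Box.from_corners(cols[0], rows[0], cols[-1] + 1, rows[-1] + 1,
                            label=cls.name)


def generate_scene(cfg: SceneConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, AnnotationRecord]:
    """Render one scene; returns (H, W, 3) uint8 image and its annotation."""
    H, W = cfg.image_size
    img = _background(cfg, rng)
    boxes: list[Box] = []
    lo_n, hi_n = cfg.instances_per_image
    n_obj = int(rng.integers(lo_n, hi_n + 1)) if hi_n >= lo_n else 0
    for _ in range(n_obj):
        ci = int(rng.choice(len(cfg.classes), p=np.asarray(cfg.mixture_weights)))
        cls = cfg.classes[ci]
        lo, hi = cls.rel_area
        rel = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        aspect = rng.uniform(*cls.aspect)
        bw = np.sqrt(rel * W * H * aspect)
        bh = np.sqrt(rel * W * H / aspect)
        bw, bh = min(bw, W - 2.0), min(bh, H - 2.0)
        exponent = rng.uniform(*cls.squareness)
        occlude = rng.random() < cfg.occlusion_prob
        placed = None
        for _try in range(cfg.max_place_tries):
            cx = rng.uniform(bw / 2 + 0.5, W - bw / 2 - 0.5)
            cy = rng.uniform(bh / 2 + 0.5, H - bh / 2 - 0.5)
            cand = Box(cx, cy, max(bw, 1.0), max(bh, 1.0), label=cls.name)
            from .metrics import iou as _iou

            overlaps = [_iou(cand, b) for b in boxes]
            cap = cfg.max_overlap if occlude else 0.0
            if all(v <= cap for v in overlaps):
                placed = (cx, cy)
                break
        if placed is None:
            log.info("skipped %s object: no placement under overlap constraint "
                     "after %d tries", cls.name, cfg.max_place_tries)
            continue
        # axis lengths chosen so the blob's tight box matches the target box
        theta = 0.0
        box = _draw_blob(img, cls, placed[0], placed[1],
                         bw / 2, bh / 2, theta, exponent, rng)
        if box is not None:
            boxes.append(box)
    record = AnnotationRecord(image_path="", width=W, height=H, boxes=boxes)
    return (img * 255).round().astype(np.uint8), record


def generate_records(n_images: int, cfg: SceneConfig,
                     ) -> list[tuple[np.ndarray, AnnotationRecord]]:
    """Generate scenes in memory; one spawned RNG stream per image."""
    seqs = np.random.SeedSequence(cfg.seed).spawn(n_images)
    out = []
    for i, sq in enumerate(seqs):
        img, rec = generate_scene(cfg, np.random.default_rng(sq))
        rec.image_path = f"images/scene_{i:05d}.png"
        out.append((img, rec))
    return out


def generate_dataset(n_images: int, cfg: SceneConfig, out_dir,
                     force: bool = False) -> dict:
    """Write a full synthetic dataset: PNGs, VOC XMLs, manifest, truth stats.

    Returns the bookkeeping dictionary also stored as ``truth_stats.json``;
    its per-class counts and mean relative sizes are computed from the boxes
    actually written, so :func:`maizedet.voc.dataset_stats` on the emitted
    files reproduces them exactly.
    """
    from PIL import Image

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True to overwrite")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)

    pairs = generate_records(n_images, cfg)
    import csv

    records = []
    with open(out / "manifest.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["image", "xml", "width", "height", "n_instances"])
        for i, (img, rec) in enumerate(pairs):
            name = f"scene_{i:05d}"
            Image.fromarray(img).save(out / "images" / f"{name}.png")
            rec.image_path = f"images/{name}.png"
            write_voc_xml(rec, out / "annotations" / f"{name}.xml")
            wr.writerow([rec.image_path, f"annotations/{name}.xml",
                         rec.width, rec.height, len(rec.boxes)])
            records.append(rec)

    stats = dataset_stats(records)
    truth = {
        "n_images": n_images,
        "seed": cfg.seed,
        "instance_counts": stats.instance_counts,
        "image_counts": stats.image_counts,
        "mean_relative_sizes": stats.mean_relative_sizes,
        "configured_mean_rel_area": {c.name: c.mean_rel_area
                                     for c in cfg.classes},
    }
    with open(out / "truth_stats.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _table1_classes(image_px: int) -> tuple[tuple[ClassSpec, ...], tuple[float, ...]]:
    specs = []
    rng_colors = np.random.default_rng(12345)  # fixed palette, not per-run
    for name in PEST_CLASSES:
        m = TABLE1_RELATIVE_SIZES[name]
        lo, hi = max(m / 2, 1.5e-3), min(m * 2, 0.6)
        color = tuple(np.clip(rng_colors.uniform(0.15, 0.95, 3), 0, 1))
        specs.append(ClassSpec(name=name, color=color, rel_area=(lo, hi)))
    counts = np.array([TABLE1_INSTANCE_COUNTS[n] for n in PEST_CLASSES], float)
    weights = tuple(counts / counts.sum())
    return tuple(specs), weights


def preset(name: str, seed: int = 0) -> SceneConfig:
    """Named scene regimes: easy, imbalanced-table1, dense-small, occluded."""
    if name == "easy":
        # two large, high-contrast, non-overlapping blob classes
        classes = (
            ClassSpec("blobA", color=(0.88, 0.25, 0.15), rel_area=(0.06, 0.20),
                      aspect=(0.8, 1.25)),
            ClassSpec("blobB", color=(0.15, 0.35, 0.90), rel_area=(0.06, 0.20),
                      aspect=(0.8, 1.25)),
        )
        return SceneConfig(image_size=(64, 64), classes=classes,
                           mixture_weights=(0.5, 0.5),
                           instances_per_image=(1, 2), occlusion_prob=0.0,
                           max_overlap=0.2, texture_level=0.08, seed=seed)
    if name == "imbalanced-table1":
        classes, weights = _table1_classes(160)
        return SceneConfig(image_size=(160, 160), classes=classes,
                           mixture_weights=weights,
                           instances_per_image=(1, 4), occlusion_prob=0.1,
                           max_overlap=0.3, texture_level=0.2, seed=seed)
    if name == "dense-small":
        classes = (
            ClassSpec("aphid", color=(0.75, 0.75, 0.3), rel_area=(0.002, 0.012)),
            ClassSpec("mite", color=(0.6, 0.2, 0.2), rel_area=(0.002, 0.012)),
        )
        return SceneConfig(image_size=(128, 128), classes=classes,
                           mixture_weights=(0.5, 0.5),
                           instances_per_image=(8, 16), occlusion_prob=0.3,
                           max_overlap=0.4, texture_level=0.25, seed=seed)
    if name == "occluded":
        classes = (
            ClassSpec("larvaA", color=(0.85, 0.55, 0.2), rel_area=(0.04, 0.15)),
            ClassSpec("larvaB", color=(0.3, 0.7, 0.6), rel_area=(0.04, 0.15)),
        )
        return SceneConfig(image_size=(96, 96), classes=classes,
                           mixture_weights=(0.5, 0.5),
                           instances_per_image=(2, 4), occlusion_prob=0.8,
                           max_overlap=0.5, texture_level=0.15, seed=seed)
    raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")


PRESETS = ("easy", "imbalanced-table1", "dense-small", "occluded")
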