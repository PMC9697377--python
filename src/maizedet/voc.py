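"""Pascal-VOC XML annotation I/O, dataset splitting and dataset statistics.

Annotation files follow the LabelImg dialect: one XML per image with
``<size>`` and one ``<object>`` per instance holding a ``<bndbox>`` in
corner form.  In memory every instance is a center-form
:class:`~maizedet.metrics.Box` — the ``(x, y, w, h, class)`` convention of
the field annotations — with corners treated as continuous positions, so
integer-coordinate files round-trip losslessly.
"""

from __future__ import annotations

import csv
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .metrics import Box, InvalidBoxError

__all__ = [
    "AnnotationRecord",
    "DatasetStats",
    "read_voc_xml",
    "write_voc_xml",
    "split_dataset",
    "relative_size",
    "dataset_stats",
    "write_manifest",
    "read_manifest",
]


class VocParseError(ValueError):
    """Malformed or incomplete VOC XML."""


@dataclass
class AnnotationRecord:
    """One image's annotation: path, pixel size, and labelled boxes."""

    image_path: str
    width: int
    height: int
    boxes: list[Box] = field(default_factory=list)

    def __post_init__(self):
        for b in self.boxes:
            if b.label in (None, ""):
                raise ValueError("annotated box must carry a nonempty class name")


def _req(parent: ET.Element, tag: str) -> ET.Element:
    el = parent.find(tag)
    if el is None:
        raise VocParseError(f"missing required tag <{tag}>")
    return el


def read_voc_xml(path) -> AnnotationRecord:
    """Parse a LabelImg-style VOC XML file into an :class:`AnnotationRecord`."""
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as e:
        raise VocParseError(f"not well-formed XML: {path}: {e}") from e
    size = _req(root, "size")
    width = int(_req(size, "width").text)
    height = int(_req(size, "height").text)
    fname_el = root.find("filename")
    image_path = fname_el.text if fname_el is not None and fname_el.text else ""
    boxes: list[Box] = []
    for obj in root.findall("object"):
        name = _req(obj, "name").text
        bb = _req(obj, "bndbox")
        xmin = float(_req(bb, "xmin").text)
        ymin = float(_req(bb, "ymin").text)
        xmax = float(_req(bb, "xmax").text)
        ymax = float(_req(bb, "ymax").text)
        if xmax <= xmin or ymax <= ymin:
            raise InvalidBoxError(
                f"{path}: degenerate box ({xmin},{ymin})-({xmax},{ymax})")
        boxes.append(Box.from_corners(xmin, ymin, xmax, ymax, label=name))
    return AnnotationRecord(image_path=image_path, width=width, height=height,
                            boxes=boxes)


def write_voc_xml(record: AnnotationRecord, path) -> None:
    """Write a record back out as LabelImg-compatible VOC XML."""
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = str(Path(record.image_path).parent) or "."
    ET.SubElement(root, "filename").text = str(record.image_path)
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(record.width)
    ET.SubElement(size, "height").text = str(record.height)
    ET.SubElement(size, "depth").text = "3"
    for b in record.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = str(b.label)
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        x1, y1, x2, y2 = b.corners
        for tag, v in (("xmin", x1), ("ymin", y1), ("xmax", x2), ("ymax", y2)):
            # integers are written without a decimal point so files
            # round-trip byte-comparably through standard tools
            ET.SubElement(bb, tag).text = (
                str(int(round(v))) if abs(v - round(v)) < 1e-9 else repr(v))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), encoding="unicode")


def split_dataset(records: Sequence, train_fraction: float = 0.9,
                  seed: int = 0) -> tuple[list, list]:
    """Random disjoint train/test partition with ``floor(f*N)`` training items."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    n = len(records)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = math.floor(train_fraction * n)
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


def relative_size(box: Box, image_w: float, image_h: float,
                  definition: str = "area") -> float:
    """Size of a box relative to its image.

    ``area`` (default) is the area ratio ``w*h / (W*H)``; ``linear`` is its
    square root, i.e. the relative linear extent.
    """
    if image_w <= 0 or image_h <= 0:
        raise ValueError(f"image must have positive area, got "
                         f"{image_w}x{image_h}")
    ratio = (box.w * box.h) / (image_w * image_h)
    if definition == "area":
        return ratio
    if definition == "linear":
        return math.sqrt(ratio)
    raise ValueError(f"unknown relative-size definition {definition!r}")


@dataclass
class DatasetStats:
    """Per-class image/instance counts and mean relative sizes."""

    image_counts: dict[str, int]
    instance_counts: dict[str, int]
    mean_relative_sizes: dict[str, float]
    size_histogram: np.ndarray
    size_bin_edges: np.ndarray

    def to_csv(self, path=None) -> str | None:
        import io

        buf = io.StringIO()
        wr = csv.writer(buf)
        wr.writerow(["class", "n_images", "n_instances", "avg_relative_size"])
        for cls in sorted(self.instance_counts):
            wr.writerow([cls, self.image_counts[cls], self.instance_counts[cls],
                         f"{self.mean_relative_sizes[cls]:.4f}"])
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def dataset_stats(records: Sequence[AnnotationRecord], n_bins: int = 30,
                  definition: str = "area") -> DatasetStats:
    """Per-class counts, mean relative size, and the global size histogram."""
    if not records:
        raise ValueError("dataset_stats requires a nonempty dataset")
    image_counts: dict[str, int] = {}
    instance_counts: dict[str, int] = {}
    sizes: dict[str, list[float]] = {}
    all_sizes: list[float] = []
    for rec in records:
        present = set()
        for b in rec.boxes:
            cls = str(b.label)
            present.add(cls)
            instance_counts[cls] = instance_counts.get(cls, 0) + 1
            r = relative_size(b, rec.width, rec.height, definition=definition)
            sizes.setdefault(cls, []).append(r)
            all_sizes.append(r)
        for cls in present:
            image_counts[cls] = image_counts.get(cls, 0) + 1
    hist, edges = np.histogram(all_sizes, bins=n_bins, range=(0.0, 1.0))
    return DatasetStats(
        image_counts=image_counts,
        instance_counts=instance_counts,
        mean_relative_sizes={c: float(np.mean(v)) for c, v in sizes.items()},
        size_histogram=hist,
        size_bin_edges=edges,
    )


def write_manifest(records: Sequence[AnnotationRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["image", "xml", "width", "height", "n_instances"])
        for rec in records:
            xml = str(Path(rec.image_path).with_suffix(".xml"))
            wr.writerow([rec.image_path, xml, rec.width, rec.height,
                         len(rec.boxes)])


def read_manifest(path) -> list[AnnotationRecord]:
    """Load the records listed in a manifest by parsing their XML files."""
    base = Path(path).parent
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(read_voc_xml(base / row["xml"]))
    return out
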