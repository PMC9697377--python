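"""Bounding boxes, overlap, detection matching and mAP evaluation.

Boxes are stored center-form ``(cx, cy, w, h)`` — the convention of the
field annotations this toolkit consumes — and converted to half-open corner
form ``[x1, x2) x [y1, y2)`` in continuous pixel coordinates for all area
arithmetic, which avoids the classic off-by-one-pixel ambiguity.

The evaluation protocol is the standard VOC-style sweep: detections sorted
by descending confidence, greedy matching against at-most-once-consumed
ground truths at an IoU threshold (strictly ``> 0.5`` by default),
cumulative precision/recall, and average precision as the area under the
monotone-envelope precision-recall curve.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Box",
    "InvalidBoxError",
    "MatchFlags",
    "PRCurve",
    "EvalReport",
    "iou",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_ap",
    "evaluate",
]


class InvalidBoxError(ValueError):
    """A box with non-positive extent or an out-of-range score."""


@dataclass
class Box:
    """One annotated or predicted region: center, size, class, confidence."""

    cx: float
    cy: float
    w: float
    h: float
    label: Hashable = None
    score: float | None = None

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(
                f"box must have positive width and height, got w={self.w}, h={self.h}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise InvalidBoxError(f"score must lie in [0,1], got {self.score}")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) of the half-open corner form."""
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @property
    def area(self) -> float:
        return self.w * self.h

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float,
                     label: Hashable = None, score: float | None = None) -> "Box":
        if x2 <= x1 or y2 <= y1:
            raise InvalidBoxError(
                f"corner box must satisfy x2 > x1 and y2 > y1, got "
                f"({x1},{y1})-({x2},{y2})")
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1,
                   label=label, score=score)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    ax1, ay1, ax2, ay2 = a.corners
    bx1, by1, bx2, by2 = b.corners
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


@dataclass
class MatchFlags:
    """TP/FP flags for detections in descending-score order."""

    flags: np.ndarray  # bool, one per detection
    n_gt: int
    order: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.n_gt < int(self.flags.sum()):
            raise ValueError(
                f"n_gt={self.n_gt} smaller than number of TP flags "
                f"({int(self.flags.sum())})")


def match_detections(dets: Sequence[Box], gts: Sequence[Box],
                     iou_thresh: float = 0.5, inclusive: bool = False) -> MatchFlags:
    """Greedily match scored detections to ground truths.

    Detections are visited in descending score (ties broken by input order);
    each ground truth is consumed at most once.  A detection is a true
    positive iff its best IoU against a still-unmatched ground truth exceeds
    ``iou_thresh`` (strictly, unless ``inclusive``).
    """
    for i, d in enumerate(dets):
        if d.score is None:
            raise ValueError(f"detection {i} carries no confidence score")
    scores = np.array([d.score for d in dets], dtype=float)
    order = np.argsort(-scores, kind="stable")
    flags = np.zeros(len(dets), dtype=bool)
    taken = np.zeros(len(gts), dtype=bool)
    for rank, di in enumerate(order):
        best_iou, best_gt = 0.0, -1
        for gi, g in enumerate(gts):
            if taken[gi]:
                continue
            v = iou(dets[di], g)
            if v > best_iou:
                best_iou, best_gt = v, gi
        hit = best_iou >= iou_thresh if inclusive else best_iou > iou_thresh
        if hit and best_gt >= 0:
            flags[rank] = True
            taken[best_gt] = True
    return MatchFlags(flags=flags, n_gt=len(gts), order=order)


class EmptyGroundTruthError(ValueError):
    """Recall is undefined: detections exist but no ground truth does."""


@dataclass
class PRCurve:
    """Cumulative precision/recall, one point per detection."""

    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self):
        self.precision = np.asarray(self.precision, dtype=float)
        self.recall = np.asarray(self.recall, dtype=float)
        if self.precision.shape != self.recall.shape:
            raise ValueError("precision and recall must have equal length")
        if len(self.recall) and np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be non-decreasing")


def precision_recall(flags: MatchFlags) -> PRCurve:
    """Cumulative precision/recall sweep over the ranked detections."""
    n = len(flags.flags)
    if flags.n_gt == 0:
        if n:
            raise EmptyGroundTruthError(
                "recall undefined: detections present but no ground truth")
        return PRCurve(np.array([]), np.array([]))
    cum_tp = np.cumsum(flags.flags)
    k = np.arange(1, n + 1)
    return PRCurve(precision=cum_tp / k, recall=cum_tp / flags.n_gt)


def average_precision(pr: PRCurve, method: str = "all_point") -> float:
    """Area under the monotone-envelope precision-recall curve, in [0, 1].

    ``all_point`` integrates the envelope exactly at every recall change
    (the VOC2010 convention); ``eleven_point`` averages the envelope at the
    11 recall levels 0.0, 0.1, ..., 1.0.
    """
    if len(pr.recall) == 0:
        warnings.warn("empty precision-recall curve; AP = 0", stacklevel=2)
        return 0.0
    # monotone non-increasing precision envelope, built right-to-left
    env = np.maximum.accumulate(pr.precision[::-1])[::-1]
    if method == "eleven_point":
        levels = np.linspace(0.0, 1.0, 11)
        vals = [env[pr.recall >= r].max() if np.any(pr.recall >= r) else 0.0
                for r in levels]
        return float(np.mean(vals))
    if method != "all_point":
        raise ValueError(f"unknown AP method {method!r}; "
                         "use 'all_point' or 'eleven_point'")
    r_prev = np.concatenate([[0.0], pr.recall[:-1]])
    return float(np.sum((pr.recall - r_prev) * env))


def mean_ap(per_class_ap: Mapping[Hashable, float]) -> float:
    """Arithmetic mean of per-class average precisions."""
    if not per_class_ap:
        raise ValueError("mean_ap requires at least one class")
    return float(np.mean(list(per_class_ap.values())))


@dataclass
class ClassMetrics:
    recall_pct: float
    ap_pct: float


@dataclass
class EvalReport:
    """Per-class recall/AP (in percent) and their means."""

    per_class: dict[Hashable, ClassMetrics]
    mean_recall_pct: float
    mean_ap_pct: float

    def to_csv(self, path=None) -> str | None:
        buf = io.StringIO()
        wr = csv.writer(buf)
        wr.writerow(["class", "recall", "ap"])
        for cls, m in self.per_class.items():
            wr.writerow([cls, f"{m.recall_pct:.1f}", f"{m.ap_pct:.1f}"])
        wr.writerow(["Mean", f"{self.mean_recall_pct:.1f}",
                     f"{self.mean_ap_pct:.1f}"])
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def to_text(self) -> str:
        width = max([len(str(c)) for c in self.per_class] + [len("Class"), 4])
        lines = [f"{'Class':<{width}}  {'Recall':>7}  {'AP':>7}"]
        for cls, m in self.per_class.items():
            lines.append(f"{str(cls):<{width}}  {m.recall_pct:>7.1f}  "
                         f"{m.ap_pct:>7.1f}")
        lines.append(f"{'Mean':<{width}}  {self.mean_recall_pct:>7.1f}  "
                     f"{self.mean_ap_pct:>7.1f}")
        return "\n".join(lines)


def evaluate(dets: Mapping[Hashable, Sequence[Box]],
             gts: Mapping[Hashable, Sequence[Box]],
             classes: Iterable[Hashable],
             iou_thresh: float = 0.5,
             inclusive: bool = False,
             ap_method: str = "all_point") -> EvalReport:
    """Multi-image, multi-class detection evaluation.

    ``dets`` and ``gts`` map an image key to its boxes; every box must carry
    a class ``label`` and every detection a ``score``.  Per class, all
    detections across images are ranked jointly by confidence and matched
    within their own image.  Reported recall is the final point of the PR
    sweep (every detection accepted) and AP the area under the enveloped
    curve, both as percentages.
    """
    classes = list(classes)
    known = set(classes)
    for key, boxes in dets.items():
        for b in boxes:
            if b.label not in known:
                raise ValueError(
                    f"detection in image {key!r} has unknown class label "
                    f"{b.label!r}; known classes: {sorted(map(str, known))}")

    image_keys = set(dets) | set(gts)
    per_class: dict[Hashable, ClassMetrics] = {}
    aps, recalls = [], []
    for cls in classes:
        records = []  # (score, image, Box), jointly ranked across images
        n_gt = 0
        gt_by_img: dict[Hashable, list[Box]] = {}
        for key in image_keys:
            g = [b for b in gts.get(key, []) if b.label == cls]
            gt_by_img[key] = g
            n_gt += len(g)
            for b in dets.get(key, []):
                if b.label == cls:
                    records.append((b.score, key, b))
        order = np.argsort(-np.array([r[0] for r in records], dtype=float),
                           kind="stable") if records else np.array([], dtype=int)
        taken = {key: np.zeros(len(g), dtype=bool)
                 for key, g in gt_by_img.items()}
        flags = np.zeros(len(records), dtype=bool)
        for rank, ri in enumerate(order):
            _, key, det = records[ri]
            best_iou, best_gt = 0.0, -1
            for gi, g in enumerate(gt_by_img[key]):
                if taken[key][gi]:
                    continue
                v = iou(det, g)
                if v > best_iou:
                    best_iou, best_gt = v, gi
            hit = best_iou >= iou_thresh if inclusive else best_iou > iou_thresh
            if hit and best_gt >= 0:
                flags[rank] = True
                taken[key][best_gt] = True
        if n_gt == 0:
            rec, ap = 0.0, 0.0
        elif len(records) == 0:
            rec, ap = 0.0, 0.0
        else:
            pr = precision_recall(MatchFlags(flags=flags, n_gt=n_gt))
            rec = float(pr.recall[-1])
            ap = average_precision(pr, method=ap_method)
        per_class[cls] = ClassMetrics(recall_pct=100.0 * rec, ap_pct=100.0 * ap)
        aps.append(100.0 * ap)
        recalls.append(100.0 * rec)
    return EvalReport(per_class=per_class,
                      mean_recall_pct=float(np.mean(recalls)),
                      mean_ap_pct=float(np.mean(aps)))
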