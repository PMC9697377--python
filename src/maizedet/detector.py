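"""Two-stage pest detector: backbone + attention pyramid + RPN + RoI heads.

The assembly follows the Faster R-CNN recipe.  A region proposal network
slides over every pyramid level scoring per-anchor objectness and box
refinements; the surviving proposals are pooled from the pyramid
(RoI-Align, level chosen by box scale) and classified by two fully
connected layers into ``c + 1`` class scores (the extra one is background)
and ``4c`` class-specific box deltas.  Training optimises the usual four
losses jointly: binary cross-entropy and smooth-L1 for the RPN,
cross-entropy and smooth-L1 for the region head.

The model object is :class:`PestDetector`; :meth:`PestDetector.fit` returns
a :class:`FitResult` holding the per-epoch loss log, a summary table and
checkpointing helpers.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, gather_rows
from .backbone import Backbone, BackboneConfig, FeatureMap, build_backbone
from .metrics import Box, EvalReport, evaluate
from .nn import SGD, Conv2d, Linear, Module, load_params, save_params
from .pyramid import AMFFP, PyramidConfig, PyramidFeatures
from .voc import AnnotationRecord

__all__ = [
    "DetectorConfig",
    "Proposal",
    "PestDetector",
    "FitResult",
    "generate_proposals",
    "roi_head",
    "clip_boxes",
    "nms",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DetectorConfig:
    """Every tunable of the two-stage assembly, Faster R-CNN conventions."""

    class_names: tuple[str, ...] = ()
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    pyramid: PyramidConfig = field(default_factory=PyramidConfig)

    levels: tuple[str, ...] = ("P2", "P3", "P4", "P5", "P6")
    anchor_scales: tuple[float, ...] = (4.0,)       # anchor size = scale*stride
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)

    rpn_pre_nms_top_n: int = 1000
    max_proposals: int = 300
    rpn_nms_thresh: float = 0.7
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    rpn_batch: int = 256
    rpn_pos_fraction: float = 0.5

    roi_pool_size: int = 7
    roi_hidden: int = 1024
    roi_pos_iou: float = 0.5
    rois_per_image: int = 512
    roi_pos_fraction: float = 0.25
    canonical_scale: float = 224.0
    canonical_level: int = 4

    score_thresh: float = 0.05
    nms_thresh: float = 0.5
    max_detections: int = 100

    lr: float = 0.01
    momentum: float = 0.9
    clip_norm: float = 10.0
    epochs: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("need at least one foreground class")

    @property
    def num_classes(self) -> int:
        return len(self.class_names)


def tiny_config(class_names: Sequence[str], seed: int = 0) -> DetectorConfig:
    """A desk-scale configuration for 64x64 scenes: small widths, few anchors."""
    return DetectorConfig(
        class_names=tuple(class_names),
        backbone=BackboneConfig(depth="tiny", deformable_stages=("C3",),
                                seed=seed),
        pyramid=PyramidConfig(channels=32, hidden_channels=8, seed=seed + 1),
        levels=("P2", "P3", "P4", "P5", "P6"),
        anchor_scales=(4.0, 5.7),
        anchor_ratios=(1.0,),
        rpn_pre_nms_top_n=200,
        max_proposals=50,
        roi_pool_size=4,
        roi_hidden=128,
        rois_per_image=64,
        canonical_scale=32.0,
        canonical_level=3,
        seed=seed,
    )


@dataclass
class Proposal:
    """A class-agnostic candidate region with its objectness and source level."""

    box: Box
    score: float
    level: str


# ---------------------------------------------------------------------------
# box utilities (corner-form float arrays, shape (N, 4) as x1,y1,x2,y2)
# ---------------------------------------------------------------------------

def clip_boxes(boxes: np.ndarray, width: float, height: float) -> np.ndarray:
    out = boxes.copy()
    out[:, 0::2] = np.clip(out[:, 0::2], 0.0, width)
    out[:, 1::2] = np.clip(out[:, 1::2], 0.0, height)
    return out


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    iw = np.maximum(ix2 - ix1, 0.0)
    ih = np.maximum(iy2 - iy1, 0.0)
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, thresh: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score order."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        ious = _iou_matrix(boxes[i:i + 1], boxes[order]).ravel()
        for j, v in zip(order, ious):
            if v > thresh and not suppressed[j]:
                suppressed[j] = True
        suppressed[i] = True
    return np.array(keep, dtype=int)


def encode_deltas(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gx = gt[:, 0] + gw / 2
    gy = gt[:, 1] + gh / 2
    return np.stack([(gx - ax) / aw, (gy - ay) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1)


def decode_deltas(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    dx, dy, dw, dh = deltas.T
    dw = np.clip(dw, -4.0, 4.0)
    dh = np.clip(dh, -4.0, 4.0)
    cx = ax + dx * aw
    cy = ay + dy * ah
    w = aw * np.exp(dw)
    h = ah * np.exp(dh)
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def make_anchors(feat_h: int, feat_w: int, stride: int,
                 scales: Sequence[float], ratios: Sequence[float]) -> np.ndarray:
    """Corner-form anchors for one level, row-major over positions then shapes."""
    ys = (np.arange(feat_h) + 0.5) * stride
    xs = (np.arange(feat_w) + 0.5) * stride
    cy, cx = np.meshgrid(ys, xs, indexing="ij")
    shapes = []
    for s in scales:
        base = s * stride
        for r in ratios:
            w = base * np.sqrt(r)
            h = base / np.sqrt(r)
            shapes.append((w, h))
    anchors = np.empty((feat_h, feat_w, len(shapes), 4))
    for k, (w, h) in enumerate(shapes):
        anchors[..., k, 0] = cx - w / 2
        anchors[..., k, 1] = cy - h / 2
        anchors[..., k, 2] = cx + w / 2
        anchors[..., k, 3] = cy + h / 2
    return anchors.reshape(-1, 4)


# ---------------------------------------------------------------------------
# network heads
# ---------------------------------------------------------------------------

class RPNHead(Module):
    def __init__(self, rng, channels: int, n_anchors: int):
        self.conv = Conv2d(rng, channels, channels, 3)
        self.cls = Conv2d(rng, channels, n_anchors, 1)
        self.reg = Conv2d(rng, channels, 4 * n_anchors, 1)

    def __call__(self, feat: Tensor) -> tuple[Tensor, Tensor]:
        h = self.conv(feat).relu()
        return self.cls(h), self.reg(h)


class RoIHead(Module):
    """Two FC layers then (c+1)-way classification and 4c-way regression."""

    def __init__(self, rng, in_dim: int, hidden: int, num_classes: int):
        self.num_classes = num_classes
        self.in_dim = in_dim
        self.fc1 = Linear(rng, in_dim, hidden)
        self.fc2 = Linear(rng, hidden, hidden)
        self.cls = Linear(rng, hidden, num_classes + 1)
        self.reg = Linear(rng, hidden, 4 * num_classes)

    def __call__(self, region_feats: Tensor) -> tuple[Tensor, Tensor]:
        if region_feats.ndim == 4:
            R = region_feats.shape[0]
            region_feats = region_feats.reshape(R, -1)
        if region_feats.shape[1] != self.in_dim:
            raise ValueError(
                f"region features have {region_feats.shape[1]} values, head "
                f"expects {self.in_dim}")
        h = self.fc2(self.fc1(region_feats).relu()).relu()
        return self.cls(h), self.reg(h)


def roi_head(region_feats: Tensor, head: RoIHead) -> tuple[Tensor, Tensor]:
    """Per region: exactly ``c+1`` class scores and ``4c`` box deltas."""
    return head(region_feats)


def roi_align(level_feat: FeatureMap, rois: np.ndarray, out_size: int) -> Tensor:
    """Pool each corner-form roi to (C, s, s) by bilinear sampling."""
    x = level_feat.values
    stride = level_feat.stride
    R = len(rois)
    s = out_size
    if R == 0:
        return Tensor(np.zeros((0, x.shape[1], s, s)))
    x1, y1, x2, y2 = rois.T
    bw = np.maximum(x2 - x1, 1e-3) / s
    bh = np.maximum(y2 - y1, 1e-3) / s
    ii = np.arange(s) + 0.5
    ys = (y1[:, None, None] + bh[:, None, None] * ii[None, :, None]) / stride - 0.5
    xs = (x1[:, None, None] + bw[:, None, None] * ii[None, None, :]) / stride - 0.5
    ys = np.broadcast_to(ys, (R, s, s)).reshape(1, -1)
    xs = np.broadcast_to(xs, (R, s, s)).reshape(1, -1)
    vals = ad.bilinear_gather(x, ys, xs)            # 1, C, R*s*s
    C = x.shape[1]
    return vals.reshape(C, R, s, s).transpose(1, 0, 2, 3)


# ---------------------------------------------------------------------------
# proposal generation
# ---------------------------------------------------------------------------

def _level_anchors(pyramid: PyramidFeatures, cfg: DetectorConfig) -> dict[str, np.ndarray]:
    out = {}
    for lvl in cfg.levels:
        fm = pyramid[lvl]
        _, _, h, w = fm.shape
        out[lvl] = make_anchors(h, w, fm.stride, cfg.anchor_scales,
                                cfg.anchor_ratios)
    return out


def generate_proposals(pyramid: PyramidFeatures, cfg: DetectorConfig,
                       rpn: RPNHead, image_size: tuple[int, int],
                       ) -> tuple[list[Proposal], dict]:
    """Score anchors on every level, decode, clip, and NMS-merge.

    Returns at most ``cfg.max_proposals`` proposals, each tagged with its
    source pyramid level, plus the raw per-level head outputs (needed for
    the training losses).  Deterministic: ties in score resolve by level
    order then anchor index.
    """
    if not list(pyramid.keys()):
        raise ValueError("empty pyramid")
    H, W = image_size
    raw: dict[str, tuple[Tensor, Tensor, np.ndarray]] = {}
    cand_boxes, cand_scores, cand_levels = [], [], []
    for lvl in cfg.levels:
        fm = pyramid[lvl]
        logits, deltas = rpn(fm.values)
        A = len(cfg.anchor_scales) * len(cfg.anchor_ratios)
        _, _, h, w = fm.shape
        anchors = make_anchors(h, w, fm.stride, cfg.anchor_scales,
                               cfg.anchor_ratios)
        raw[lvl] = (logits, deltas, anchors)
        # flatten logits to anchor order (position-major, shape-minor)
        lg = logits.data.reshape(A, h * w).T.reshape(-1)
        dl = deltas.data.reshape(A, 4, h * w).transpose(2, 0, 1).reshape(-1, 4)
        k = min(cfg.rpn_pre_nms_top_n, len(lg))
        top = np.argsort(-lg, kind="stable")[:k]
        boxes = decode_deltas(anchors[top], dl[top])
        boxes = clip_boxes(boxes, W, H)
        ok = ((boxes[:, 2] - boxes[:, 0]) >= 1.0) & \
             ((boxes[:, 3] - boxes[:, 1]) >= 1.0)
        cand_boxes.append(boxes[ok])
        cand_scores.append(lg[top][ok])
        cand_levels.extend([lvl] * int(ok.sum()))
    boxes = np.concatenate(cand_boxes) if cand_boxes else np.zeros((0, 4))
    scores = np.concatenate(cand_scores) if cand_scores else np.zeros(0)
    keep = nms(boxes, scores, cfg.rpn_nms_thresh)[:cfg.max_proposals]
    props = []
    sig = 1.0 / (1.0 + np.exp(-scores[keep]))
    for i, k_ in enumerate(keep):
        b = boxes[k_]
        props.append(Proposal(
            box=Box.from_corners(*b, score=float(sig[i])),
            score=float(sig[i]), level=cand_levels[k_]))
    return props, raw


def _assign_level(rois: np.ndarray, cfg: DetectorConfig) -> np.ndarray:
    """FPN heuristic: larger boxes pool from coarser levels."""
    w = rois[:, 2] - rois[:, 0]
    h = rois[:, 3] - rois[:, 1]
    k = np.floor(cfg.canonical_level +
                 np.log2(np.sqrt(np.maximum(w * h, 1e-6)) / cfg.canonical_scale))
    lo = int(cfg.levels[0][1:])
    hi = int(cfg.levels[-1][1:])
    return np.clip(k, lo, hi).astype(int)


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class PestDetector(Module):
    """The assembled two-stage detector (statsmodels-style model object).

    Construct from a :class:`DetectorConfig`, then either :meth:`fit` on a
    list of annotated images or :meth:`detect` with loaded parameters.
    """

    def __init__(self, cfg: DetectorConfig):
        if cfg.num_classes < 1:
            raise ValueError("detector needs at least one class")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed + 7)
        self.backbone: Backbone = build_backbone(cfg.backbone)
        self.neck = AMFFP(cfg.pyramid, self.backbone.out_channels)
        d = cfg.pyramid.channels
        A = len(cfg.anchor_scales) * len(cfg.anchor_ratios)
        self.rpn = RPNHead(rng, d, A)
        self.head = RoIHead(rng, d * cfg.roi_pool_size ** 2, cfg.roi_hidden,
                            cfg.num_classes)

    # -- forward pieces ----------------------------------------------------

    def _prep_image(self, image: np.ndarray) -> Tensor:
        img = np.asarray(image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise IOError(f"expected an H x W x 3 image, got shape {img.shape}")
        x = img.astype(np.float64) / 255.0
        x = (x - 0.5) * 2.0
        return Tensor(x.transpose(2, 0, 1)[None])

    def forward_pyramid(self, image: np.ndarray) -> PyramidFeatures:
        return self.neck(self.backbone(self._prep_image(image)))

    def _pool(self, pyramid: PyramidFeatures, rois: np.ndarray) -> Tensor:
        lvls = _assign_level(rois, self.cfg)
        pieces, perm = [], []
        for lvl_num in sorted(set(lvls.tolist())):
            idx = np.flatnonzero(lvls == lvl_num)
            feats = roi_align(pyramid[f"P{lvl_num}"], rois[idx],
                              self.cfg.roi_pool_size)
            pieces.append(feats)
            perm.extend(idx.tolist())
        pooled = concat(pieces, axis=0) if len(pieces) > 1 else pieces[0]
        inv = np.argsort(np.array(perm))
        return gather_rows(pooled, inv)

    # -- inference ---------------------------------------------------------

    def detect(self, image: np.ndarray,
               score_thresh: float | None = None) -> list[Box]:
        """Detect pests in one image; boxes in original pixel coordinates."""
        cfg = self.cfg
        thresh = cfg.score_thresh if score_thresh is None else score_thresh
        H, W = np.asarray(image).shape[:2]
        pyramid = self.forward_pyramid(image)
        props, _ = generate_proposals(pyramid, cfg, self.rpn, (H, W))
        if not props:
            return []
        rois = np.array([p.box.corners for p in props])
        scores_t, deltas_t = roi_head(self._pool(pyramid, rois), self.head)
        z = scores_t.data - scores_t.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)      # R, c+1
        deltas = deltas_t.data.reshape(len(rois), cfg.num_classes, 4)
        detections: list[Box] = []
        for ci, name in enumerate(cfg.class_names):
            p = probs[:, ci + 1]
            boxes = decode_deltas(rois, deltas[:, ci])
            boxes = clip_boxes(boxes, W, H)
            ok = (p > thresh) & ((boxes[:, 2] - boxes[:, 0]) >= 1.0) \
                & ((boxes[:, 3] - boxes[:, 1]) >= 1.0)
            if not ok.any():
                continue
            bk, pk = boxes[ok], p[ok]
            keep = nms(bk, pk, cfg.nms_thresh)
            for k in keep:
                detections.append(Box.from_corners(*bk[k], label=name,
                                                   score=float(pk[k])))
        detections.sort(key=lambda b: -b.score)
        return detections[:cfg.max_detections]

    # -- training ----------------------------------------------------------

    def _losses(self, image: np.ndarray, gts: Sequence[Box],
                rng: np.random.Generator) -> dict[str, Tensor]:
        cfg = self.cfg
        H, W = np.asarray(image).shape[:2]
        gt_boxes = np.array([b.corners for b in gts], dtype=float)
        gt_labels = np.array(
            [cfg.class_names.index(b.label) + 1 for b in gts], dtype=int)
        pyramid = self.forward_pyramid(image)
        props, raw = generate_proposals(pyramid, cfg, self.rpn, (H, W))

        # ---- RPN targets over all anchors of all levels
        logit_list, delta_list, anchor_list = [], [], []
        for lvl in cfg.levels:
            logits, deltas, anchors = raw[lvl]
            A = len(cfg.anchor_scales) * len(cfg.anchor_ratios)
            _, _, h, w = logits.shape
            logit_list.append(
                logits.reshape(A, h * w).transpose(1, 0).reshape(-1))
            delta_list.append(
                deltas.reshape(A, 4, h * w).transpose(2, 0, 1).reshape(-1, 4))
            anchor_list.append(anchors)
        logits_all = concat(logit_list, axis=0)
        deltas_all = concat(delta_list, axis=0)
        anchors_all = np.concatenate(anchor_list)

        iou = _iou_matrix(anchors_all, gt_boxes)
        best_gt = iou.argmax(axis=1)
        best_iou = iou.max(axis=1)
        labels = -np.ones(len(anchors_all))           # -1 = ignore
        labels[best_iou < cfg.rpn_neg_iou] = 0.0
        labels[best_iou >= cfg.rpn_pos_iou] = 1.0
        # every ground truth claims its best-overlapping anchor
        for gi in range(len(gt_boxes)):
            cand = np.flatnonzero(iou[:, gi] >= iou[:, gi].max() - 1e-9)
            labels[cand] = 1.0
            best_gt[cand] = gi

        pos = np.flatnonzero(labels == 1.0)
        neg = np.flatnonzero(labels == 0.0)
        n_pos = min(len(pos), int(cfg.rpn_batch * cfg.rpn_pos_fraction))
        n_neg = min(len(neg), cfg.rpn_batch - n_pos)
        pos = rng.permutation(pos)[:n_pos]
        neg = rng.permutation(neg)[:n_neg]
        sample = np.concatenate([pos, neg])
        rpn_cls = ad.bce_with_logits(gather_rows(logits_all, sample),
                                     (labels[sample] == 1.0).astype(float))
        if len(pos):
            tgt = encode_deltas(anchors_all[pos], gt_boxes[best_gt[pos]])
            rpn_reg = ad.smooth_l1(gather_rows(deltas_all, pos), tgt, beta=1.0 / 9)
        else:
            rpn_reg = Tensor(0.0)

        # ---- RoI targets: proposals plus the ground-truth boxes themselves
        prop_boxes = np.array([p.box.corners for p in props]) \
            if props else np.zeros((0, 4))
        rois = np.concatenate([prop_boxes, gt_boxes])
        riou = _iou_matrix(rois, gt_boxes)
        r_best = riou.argmax(axis=1)
        r_iou = riou.max(axis=1)
        roi_labels = np.where(r_iou >= cfg.roi_pos_iou,
                              gt_labels[r_best], 0)
        fg = np.flatnonzero(roi_labels > 0)
        bg = np.flatnonzero(roi_labels == 0)
        n_fg = min(len(fg), int(cfg.rois_per_image * cfg.roi_pos_fraction))
        n_bg = min(len(bg), cfg.rois_per_image - n_fg)
        fg = rng.permutation(fg)[:n_fg]
        bg = rng.permutation(bg)[:n_bg]
        sel = np.concatenate([fg, bg])
        rois_sel = rois[sel]
        lbl_sel = roi_labels[sel]

        scores_t, deltas_t = roi_head(self._pool(pyramid, rois_sel), self.head)
        roi_cls = ad.softmax_cross_entropy(scores_t, lbl_sel)
        fg_rows = np.flatnonzero(lbl_sel > 0)
        if len(fg_rows):
            cls_idx = lbl_sel[fg_rows] - 1
            cols = np.stack([4 * cls_idx + k for k in range(4)], axis=1)
            sel_deltas = gather_rows(deltas_t, fg_rows)
            picked = sel_deltas[np.arange(len(fg_rows))[:, None], cols]
            tgt = encode_deltas(rois_sel[fg_rows],
                                gt_boxes[r_best[sel][fg_rows]])
            roi_reg = ad.smooth_l1(picked, tgt, beta=1.0)
        else:
            roi_reg = Tensor(0.0)

        return {"rpn_cls": rpn_cls, "rpn_reg": rpn_reg,
                "roi_cls": roi_cls, "roi_reg": roi_reg}

    def fit(self, dataset: Sequence[tuple[np.ndarray, AnnotationRecord]],
            epochs: int | None = None, lr: float | None = None,
            resume_from=None, log_fn=None) -> "FitResult":
        """Train on (image, annotation) pairs; returns the fit log.

        The shuffle order, target sampling and parameter initialisation all
        derive from ``cfg.seed``; per-epoch RNG streams are keyed by
        ``(seed, epoch)`` and checkpoints carry the optimiser's momentum
        buffers, so a run resumed with ``resume_from`` continues exactly as
        the uninterrupted run would.
        """
        cfg = self.cfg
        if not any(len(rec.boxes) for _, rec in dataset):
            raise ValueError("training dataset contains no annotations")
        for _, rec in dataset:
            for b in rec.boxes:
                if b.label not in cfg.class_names:
                    raise ValueError(f"unknown class {b.label!r} in dataset")
        epochs = cfg.epochs if epochs is None else epochs
        lr = cfg.lr if lr is None else lr
        opt = SGD(self.params(), lr=lr, momentum=cfg.momentum,
                  clip_norm=cfg.clip_norm)
        start_epoch = 0
        if resume_from is not None:
            meta = self.load(resume_from)
            start_epoch = int(meta.get("epoch", -1)) + 1
            state, _ = load_params(resume_from)
            for i, v in enumerate(opt.vel):
                key = f"__vel__{i}"
                if key in state:
                    v[...] = state[key]
        history: list[dict] = []
        for epoch in range(start_epoch, epochs):
            erng = np.random.default_rng(
                np.random.SeedSequence((cfg.seed, epoch)))
            order = erng.permutation(len(dataset))
            comp_sums = {"rpn_cls": 0.0, "rpn_reg": 0.0,
                         "roi_cls": 0.0, "roi_reg": 0.0}
            total, t0 = 0.0, time.time()
            for idx in order:
                image, rec = dataset[idx]
                if not rec.boxes:
                    continue
                losses = self._losses(image, rec.boxes, erng)
                loss = (losses["rpn_cls"] + losses["rpn_reg"]
                        + losses["roi_cls"] + losses["roi_reg"])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: "
                        f"{ {k: float(v.data) for k, v in losses.items()} }")
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data)
                for k, v in losses.items():
                    comp_sums[k] += float(v.data)
            n = max(1, len([1 for _, r in dataset if r.boxes]))
            entry = {"epoch": epoch, "loss": total / n,
                     **{k: v / n for k, v in comp_sums.items()},
                     "seconds": time.time() - t0}
            history.append(entry)
            if log_fn is not None:
                log_fn(entry)
        return FitResult(model=self, history=history,
                         optimizer_state=[v.copy() for v in opt.vel])

    # -- persistence ---------------------------------------------------------

    def save(self, path, epoch: int | None = None,
             velocities: list[np.ndarray] | None = None) -> None:
        state = self.state_dict()
        for i, v in enumerate(velocities or []):
            state[f"__vel__{i}"] = v
        save_params(path, state,
                    class_names=list(self.cfg.class_names),
                    epoch=-1 if epoch is None else epoch)

    def load(self, path) -> dict:
        state, meta = load_params(path)
        self.load_state_dict(state)
        return meta

    def evaluate_on(self, dataset: Sequence[tuple[np.ndarray, AnnotationRecord]],
                    iou_thresh: float = 0.5,
                    score_thresh: float | None = None) -> EvalReport:
        dets = {i: self.detect(img, score_thresh=score_thresh)
                for i, (img, _) in enumerate(dataset)}
        gts = {i: rec.boxes for i, (_, rec) in enumerate(dataset)}
        return evaluate(dets, gts, self.cfg.class_names, iou_thresh=iou_thresh)


@dataclass
class FitResult:
    """Training log and handle to the fitted detector."""

    model: PestDetector
    history: list[dict]
    optimizer_state: list[np.ndarray] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.history[-1]["loss"] if self.history else float("nan")

    def save(self, path) -> None:
        last = self.history[-1]["epoch"] if self.history else -1
        self.model.save(path, epoch=last, velocities=self.optimizer_state)

    def summary(self) -> str:
        lines = ["Two-stage pest detector fit",
                 f"  classes: {', '.join(self.model.cfg.class_names)}",
                 f"  parameters: {self.model.n_params():,d}",
                 f"{'epoch':>5}  {'loss':>9}  {'rpn_cls':>8}  {'rpn_reg':>8}"
                 f"  {'roi_cls':>8}  {'roi_reg':>8}"]
        for e in self.history:
            lines.append(f"{e['epoch']:>5}  {e['loss']:>9.4f}  "
                         f"{e['rpn_cls']:>8.4f}  {e['rpn_reg']:>8.4f}  "
                         f"{e['roi_cls']:>8.4f}  {e['roi_reg']:>8.4f}")
        return "\n".join(lines)
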