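"""Residual feature extractor with deformable 3x3 convolutions.

A deformable convolution augments the regular sampling grid with learned
per-position, per-tap 2-D offsets:

    y(l0) = sum_{ln in Omega} w(ln) * x(l0 + ln + Dln)

where the fractional locations are read with the separable bilinear tent
kernel G(k,l) = max(0, 1-|kx-lx|) * max(0, 1-|ky-ly|) (zero outside the
grid).  The offset field Dln is itself predicted by an ordinary 3x3
convolution over the same input, zero-initialised so an untrained
deformable layer is exactly a regular convolution; offsets then learn by
backpropagation like every other weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .autodiff import Tensor, as_tensor, bilinear_gather, conv2d
from .nn import Conv2d, Module

__all__ = [
    "FeatureMap",
    "BackboneConfig",
    "bilinear_sample",
    "predict_offsets",
    "deformable_conv2d",
    "DeformConv2d",
    "Backbone",
    "build_backbone",
    "BACKBONE_VARIANTS",
]

_ALLOWED_STRIDES = {1, 2, 4, 8, 16, 32, 64}


@dataclass
class FeatureMap:
    """A (N, C, H, W) activation grid at a known stride w.r.t. the image."""

    values: Tensor
    stride: int = 1

    def __post_init__(self):
        self.values = as_tensor(self.values)
        if self.values.ndim == 3:  # accept C,H,W and add the batch axis
            self.values = self.values.reshape((1,) + self.values.shape)
        if self.values.ndim != 4:
            raise ValueError(f"FeatureMap needs a 3- or 4-d grid, got "
                             f"{self.values.ndim} dims")
        if self.stride not in _ALLOWED_STRIDES:
            raise ValueError(f"stride must be one of {sorted(_ALLOWED_STRIDES)}")

    @property
    def shape(self):
        return self.values.shape


def _grid_of(x) -> np.ndarray:
    if isinstance(x, FeatureMap):
        x = x.values
    if isinstance(x, Tensor):
        x = x.data
    x = np.asarray(x, dtype=float)
    if x.ndim == 4:
        x = x[0]
    if x.ndim == 2:
        x = x[None]
    return x


def bilinear_sample(x, l, channel: int = 0) -> float:
    """Evaluate one feature channel at a continuous (y, x) location.

    Implements the tent-kernel sum directly: each of the four surrounding
    pixels contributes its value weighted by
    ``max(0,1-|ky-ly|) * max(0,1-|kx-lx|)``; pixels outside the grid
    contribute zero, which realises zero padding.
    """
    ly, lx = float(l[0]), float(l[1])
    if not (np.isfinite(ly) and np.isfinite(lx)):
        raise ValueError(f"sampling location must be finite, got {l}")
    grid = _grid_of(x)[channel]
    H, W = grid.shape
    y0, x0 = int(np.floor(ly)), int(np.floor(lx))
    val = 0.0
    for ky in (y0, y0 + 1):
        for kx in (x0, x0 + 1):
            wgt = max(0.0, 1.0 - abs(ky - ly)) * max(0.0, 1.0 - abs(kx - lx))
            if wgt > 0.0 and 0 <= ky < H and 0 <= kx < W:
                val += wgt * grid[ky, kx]
    return float(val)


def predict_offsets(x, offset_conv: Conv2d, n_taps: int = 9) -> Tensor:
    """Predict the per-tap offset field with a regular 3x3 convolution.

    The offset head is a stride-1, pad-1, dilation-1 convolution, so the
    offset field has exactly the spatial size of its input; its channel
    count must be ``2 * n_taps`` ((dy, dx) per kernel tap).
    """
    xt = x.values if isinstance(x, FeatureMap) else as_tensor(x)
    out = offset_conv(xt)
    if out.shape[1] != 2 * n_taps:
        raise ValueError(
            f"offset head produces {out.shape[1]} channels, expected "
            f"{2 * n_taps} for {n_taps} kernel taps")
    return out


def deformable_conv2d(x, w, offsets, b=None, pad: int | None = None) -> Tensor:
    """Deformable 2-D convolution via explicit bilinear sampling.

    Parameters
    ----------
    x : (N, C, H, W) tensor or FeatureMap
    w : (F, C, k, k) kernel weights
    offsets : (N, 2*k*k, H, W) displacement field, ordered ``(dy, dx)`` per
        tap in row-major kernel order; one offset pair per tap, shared
        across input channels.
    """
    xt = x.values if isinstance(x, FeatureMap) else as_tensor(x)
    w = as_tensor(w)
    off = as_tensor(offsets)
    if not np.isfinite(off.data).all():
        raise ValueError("offset field contains non-finite values")
    N, C, H, W = xt.shape
    F, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"weight expects {Cw} input channels, input has {C}")
    K = kh * kw
    if off.shape != (N, 2 * K, H, W):
        raise ValueError(
            f"offset field has shape {off.shape}, expected {(N, 2 * K, H, W)}")
    if pad is None:
        pad = kh // 2

    # base sampling grid: l0 + ln for every output position and tap
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    taps = np.stack(np.mgrid[0:kh, 0:kw], axis=-1).reshape(K, 2) - pad
    base_y = (ys[None] + taps[:, 0, None, None]).reshape(1, K * H * W)
    base_x = (xs[None] + taps[:, 1, None, None]).reshape(1, K * H * W)

    off5 = off.reshape(N, K, 2, H, W)
    dy = off5[:, :, 0].reshape(N, K * H * W)
    dx = off5[:, :, 1].reshape(N, K * H * W)
    samp_y = dy + base_y
    samp_x = dx + base_x

    vals = bilinear_gather(xt, samp_y, samp_x)         # N, C, K*H*W
    vals = vals.reshape(N, C, K, H * W).reshape(N, C * K, H * W)
    wmat = w.reshape(F, C * K)
    y = wmat.matmul(vals).reshape(N, F, H, W)
    if b is not None:
        y = y + as_tensor(b).reshape(1, F, 1, 1)
    return y


class DeformConv2d(Module):
    """3x3 deformable convolution with its zero-initialised offset head."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 k: int = 3):
        from .nn import he_init

        self.k = k
        self.w = Tensor(he_init(rng, (cout, cin, k, k), cin * k * k),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.offset_conv = Conv2d(rng, cin, 2 * k * k, 3, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        off = predict_offsets(x, self.offset_conv, n_taps=self.k * self.k)
        return deformable_conv2d(x, self.w, off, b=self.b)


# ---------------------------------------------------------------------------
# residual backbone
# ---------------------------------------------------------------------------

BACKBONE_VARIANTS: dict[str, dict] = {
    # widths/blocks per stage C2..C5
    "tiny": {"widths": (16, 24, 32, 32), "blocks": (1, 1, 1, 1)},
    "resnet18": {"widths": (64, 128, 256, 512), "blocks": (2, 2, 2, 2)},
    "resnet50": {"widths": (64, 128, 256, 512), "blocks": (3, 4, 6, 3)},
}

_STAGES = ("C2", "C3", "C4", "C5")


@dataclass
class BackboneConfig:
    """Which residual variant to build and where to use deformable taps."""

    depth: str = "resnet50"
    deformable_stages: tuple[str, ...] = ("C3", "C4", "C5")
    deformable: bool = True
    widths: tuple[int, ...] | None = None   # override the variant's widths
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.depth not in BACKBONE_VARIANTS:
            raise ValueError(
                f"unknown backbone depth {self.depth!r}; supported variants: "
                f"{sorted(BACKBONE_VARIANTS)}")
        bad = set(self.deformable_stages) - set(_STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}; use {_STAGES}")
        if self.deformable and not self.deformable_stages:
            raise ValueError(
                "deformable mode enabled but no stage marked deformable")


class _BasicBlock(Module):
    def __init__(self, rng, cin, cout, stride, deformable):
        self.conv1 = Conv2d(rng, cin, cout, 3, stride=stride)
        if deformable:
            self.conv2 = DeformConv2d(rng, cout, cout, 3)
        else:
            self.conv2 = Conv2d(rng, cout, cout, 3)
        self.proj = (Conv2d(rng, cin, cout, 1, stride=stride, bias=False)
                     if (stride != 1 or cin != cout) else None)

    def __call__(self, x):
        h = self.conv2(self.conv1(x).relu())
        shortcut = self.proj(x) if self.proj is not None else x
        return (h + shortcut).relu()


class Backbone(Module):
    """Stem + four residual stages producing C2..C5 at strides 4..32."""

    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        variant = BACKBONE_VARIANTS[cfg.depth]
        widths = cfg.widths or variant["widths"]
        blocks = variant["blocks"]
        rng = np.random.default_rng(cfg.seed)
        self.stem = Conv2d(rng, cfg.in_channels, widths[0], 3, stride=2)
        self.stages = []
        cin = widths[0]
        for si, (wd, nb) in enumerate(zip(widths, blocks)):
            deform = cfg.deformable and _STAGES[si] in cfg.deformable_stages
            stage = []
            for bi in range(nb):
                stage.append(_BasicBlock(rng, cin, wd, stride=2 if bi == 0 else 1,
                                         deformable=deform))
                cin = wd
            self.stages.append(stage)
        self.out_channels = {s: w for s, w in zip(_STAGES, widths)}

    def __call__(self, image: Tensor) -> dict[str, FeatureMap]:
        x = self.stem(as_tensor(image)).relu()
        feats: dict[str, FeatureMap] = {}
        stride = 2
        for name, stage in zip(_STAGES, self.stages):
            for block in stage:
                x = block(x)
            stride *= 2
            feats[name] = FeatureMap(x, stride=stride)
        return feats


def build_backbone(cfg: BackboneConfig) -> Backbone:
    """Construct the configured residual feature extractor."""
    return Backbone(cfg)
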