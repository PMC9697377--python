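"""Attention-weighted multi-scale feature-fusion pyramid (AMFFP).

A plain feature pyramid fuses adjacent backbone stages as

    P_i = B_i(X_i) + alpha * F_up(P_{i+1})

with the fusion factor alpha fixed at 1.  Here alpha is instead *learned
per level and per pixel*: the 2x-upsampled upper map is fed through a small
weight generator — 1x1 conv, ReLU, 3x3 conv, sigmoid — whose output in
(0, 1) gates the top-down pathway before the addition.  Each fused level
then passes a 3x3 smoothing convolution to suppress upsampling aliasing,
and P6 extends the pyramid by stride-2 subsampling of P5.

Because the sigmoid never reaches 1 exactly, an explicit ``alpha_bypass``
flag forces alpha to 1, which reduces the module numerically to a plain
FPN — useful for equivalence testing and ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, max_subsample2x, upsample2x_nearest
from .backbone import FeatureMap
from .nn import Conv2d, Module

__all__ = [
    "PyramidConfig",
    "PyramidFeatures",
    "WeightGenerator",
    "lateral_project",
    "fuse_level",
    "AMFFP",
    "build_pyramid",
]

_STAGE_ORDER = ("C2", "C3", "C4", "C5")


@dataclass
class PyramidConfig:
    channels: int = 256            # common width d of all pyramid levels
    attention: bool = True
    attention_channels: int = 1    # 1 = one alpha per pixel; or d = per channel
    hidden_channels: int | None = None  # generator width; default d // 4
    alpha_bypass: bool = False     # force alpha = 1 (plain FPN behaviour)
    literal_subsample_variant: bool = False  # laterals C2..C4, P5+P6 subsampled
    seed: int = 0


@dataclass
class PyramidFeatures:
    """Fused levels P2..P6 plus the per-level attention maps used."""

    levels: dict[str, FeatureMap]
    alpha_maps: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, key: str) -> FeatureMap:
        return self.levels[key]

    def keys(self):
        return self.levels.keys()


def lateral_project(ci, proj: Conv2d) -> Tensor:
    """1x1 channel projection onto the pyramid width; spatial size kept."""
    x = ci.values if isinstance(ci, FeatureMap) else as_tensor(ci)
    if proj.w.shape[2:] != (1, 1):
        raise ValueError("lateral projection must be a 1x1 convolution")
    if proj.w.shape[1] != x.shape[1]:
        raise ValueError(
            f"lateral projection expects {proj.w.shape[1]} channels, "
            f"feature map has {x.shape[1]}")
    return proj(x)


class WeightGenerator(Module):
    """conv1x1 -> ReLU -> conv3x3 -> sigmoid; outputs strictly inside (0,1)."""

    def __init__(self, rng: np.random.Generator, channels: int,
                 hidden: int, out_channels: int = 1):
        self.conv1 = Conv2d(rng, channels, hidden, 1)
        self.conv3 = Conv2d(rng, hidden, out_channels, 3)

    def __call__(self, upsampled: Tensor) -> Tensor:
        return self.conv3(self.conv1(upsampled).relu()).sigmoid()


def attention_weights(upsampled, gen: WeightGenerator) -> Tensor:
    """Generate the fusion weight map alpha for one pyramid level."""
    x = upsampled.values if isinstance(upsampled, FeatureMap) else as_tensor(upsampled)
    return gen(x)


def fuse_level(lateral, upper_upsampled, alpha) -> Tensor:
    """Gated top-down fusion: lateral + alpha * upsampled upper level."""
    lat = lateral.values if isinstance(lateral, FeatureMap) else as_tensor(lateral)
    up = (upper_upsampled.values if isinstance(upper_upsampled, FeatureMap)
          else as_tensor(upper_upsampled))
    if lat.shape != up.shape:
        raise ValueError(f"cannot fuse shapes {lat.shape} and {up.shape}")
    return lat + as_tensor(alpha) * up


class AMFFP(Module):
    """The five-level attention pyramid over backbone stages C2..C5."""

    def __init__(self, cfg: PyramidConfig, in_channels: dict[str, int]):
        self.cfg = cfg
        d = cfg.channels
        hidden = cfg.hidden_channels or max(1, d // 4)
        rng = np.random.default_rng(cfg.seed)
        lateral_stages = (_STAGE_ORDER[:-1] if cfg.literal_subsample_variant
                          else _STAGE_ORDER)
        self.lateral_stages = lateral_stages
        self.laterals = [Conv2d(rng, in_channels[s], d, 1) for s in lateral_stages]
        # one smoothing conv per fused output level
        self.smooth = [Conv2d(rng, d, d, 3) for _ in lateral_stages]
        out_ch = cfg.attention_channels
        if out_ch not in (1, d):
            raise ValueError(f"attention_channels must be 1 or d={d}")
        self.generators = [WeightGenerator(rng, d, hidden, out_ch)
                           for _ in lateral_stages[:-1]]

    def __call__(self, stage_feats: dict[str, FeatureMap]) -> PyramidFeatures:
        missing = [s for s in self.lateral_stages if s not in stage_feats]
        if missing:
            raise ValueError(f"pyramid needs stages {self.lateral_stages}, "
                             f"missing {missing}")
        cfg = self.cfg
        laterals = [lateral_project(stage_feats[s], conv)
                    for s, conv in zip(self.lateral_stages, self.laterals)]
        strides = [stage_feats[s].stride for s in self.lateral_stages]

        fused = [None] * len(laterals)
        fused[-1] = laterals[-1]
        alpha_maps: dict[str, np.ndarray] = {}
        for i in range(len(laterals) - 2, -1, -1):
            up = upsample2x_nearest(fused[i + 1])
            level_name = f"P{i + 2}"
            if cfg.alpha_bypass or not cfg.attention:
                alpha = Tensor(np.ones((1, 1, 1, 1)))
            else:
                alpha = attention_weights(up, self.generators[i])
            alpha_maps[level_name] = np.broadcast_to(
                alpha.data, (up.shape[0], alpha.shape[1]) + up.shape[2:]).copy()
            fused[i] = fuse_level(laterals[i], up, alpha)

        levels: dict[str, FeatureMap] = {}
        for i, (f, s) in enumerate(zip(fused, strides)):
            levels[f"P{i + 2}"] = FeatureMap(self.smooth[i](f), stride=s)

        top_name = f"P{len(levels) + 1}"  # P5 in the standard layout
        top = levels[top_name]
        if cfg.literal_subsample_variant:
            p5 = FeatureMap(max_subsample2x(top.values), stride=top.stride * 2)
            levels["P5"] = p5
            levels["P6"] = FeatureMap(max_subsample2x(p5.values),
                                      stride=p5.stride * 2)
        else:
            levels["P6"] = FeatureMap(max_subsample2x(top.values),
                                      stride=top.stride * 2)
        return PyramidFeatures(levels=levels, alpha_maps=alpha_maps)


def build_pyramid(stage_feats: dict[str, FeatureMap],
                  params: AMFFP) -> PyramidFeatures:
    """Fuse backbone stage features into the five pyramid outputs P2..P6."""
    return params(stage_feats)
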