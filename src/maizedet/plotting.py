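"""Precision-recall curve and attention-map rendering."""

from __future__ import annotations

import numpy as np

from .metrics import PRCurve

__all__ = ["plot_pr_curve", "save_alpha_heatmap"]


def plot_pr_curve(pr: PRCurve, ax=None, label: str | None = None,
                  show_envelope: bool = True):
    """Plot a precision-recall sweep and its monotone envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.step(pr.recall, pr.precision, where="post", label=label)
    if show_envelope and len(pr.precision):
        env = np.maximum.accumulate(pr.precision[::-1])[::-1]
        ax.step(pr.recall, env, where="post", linestyle="--", alpha=0.6)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    if label:
        ax.legend()
    return ax


def save_alpha_heatmap(alpha: np.ndarray, path) -> None:
    """Write one attention weight map as a grayscale PNG (for inspection)."""
    from PIL import Image

    a = np.asarray(alpha, dtype=float)
    while a.ndim > 2:  # drop batch/channel axes by averaging
        a = a.mean(axis=0)
    lo, hi = float(a.min()), float(a.max())
    scaled = (a - lo) / (hi - lo) if hi > lo else np.full_like(a, 0.5)
    Image.fromarray((scaled * 255).astype(np.uint8)).save(path)
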