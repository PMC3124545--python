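"""Rendering helpers: deformation grids and relative-warp scatter plots.

Kept deliberately thin — figures are diagnostics, not results.  All
functions accept a Matplotlib ``Axes`` or create one, and return the
figure so callers can save SVG/PNG.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .warps import tps_deformation_grid  # noqa: E402


def plot_deformation_grid(reference: np.ndarray, target: np.ndarray,
                          resolution: int = 20, ax=None):
    """Thin-plate-spline deformation of ``reference`` onto ``target``,
    drawn as the warped grid with landmarks overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    grid, warped = tps_deformation_grid(reference, target,
                                        resolution=resolution)
    w = warped.reshape(resolution, resolution, 2)
    for i in range(resolution):
        ax.plot(w[i, :, 0], w[i, :, 1], color="0.7", lw=0.5)
        ax.plot(w[:, i, 0], w[:, i, 1], color="0.7", lw=0.5)
    ax.scatter(target[:, 0], target[:, 1], s=12, color="k", zorder=3)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax.figure


def plot_relative_warps(scores: np.ndarray, variance_fraction: np.ndarray,
                        labels=None, groups=None, ax=None):
    """Specimens on the first two relative warps, axes annotated with the
    variance each explains."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if groups is not None:
        unique = sorted(set(groups))
        for g in unique:
            idx = [i for i, gg in enumerate(groups) if gg == g]
            ax.scatter(scores[idx, 0], scores[idx, 1], s=18, label=g)
        ax.legend(fontsize=7, frameon=False)
    else:
        ax.scatter(scores[:, 0], scores[:, 1], s=18, color="k")
    if labels is not None:
        for i, lab in enumerate(labels):
            ax.annotate(lab, scores[i, :2], fontsize=6,
                        textcoords="offset points", xytext=(2, 2))
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel(f"RW1 ({variance_fraction[0] * 100:.1f}%)")
    ax.set_ylabel(f"RW2 ({variance_fraction[1] * 100:.1f}%)")
    return ax.figure
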