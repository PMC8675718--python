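"""Minimal plotting helpers: dissimilarity heatmap and reference-map scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_dissimilarity_heatmap", "plot_reference_map"]


def plot_dissimilarity_heatmap(D: pd.DataFrame, row_order=None, col_order=None,
                               path=None, ax=None):
    """Clustered cell-line x tumour heatmap, colour range fixed to [0, 2]."""
    if row_order is not None:
        D = D.iloc[row_order]
    if col_order is not None:
        D = D.iloc[:, col_order]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(D.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0.0, vmax=2.0)
    ax.set_xlabel("tumours")
    ax.set_ylabel("cell lines")
    plt.colorbar(im, ax=ax, label="cosine dissimilarity")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_reference_map(corners: np.ndarray, sample_coords: pd.DataFrame,
                       path=None, ax=None):
    """Corner skeleton with subtype-coloured sample dots."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for subtype, grp in sample_coords.groupby("subtype"):
        ax.scatter(grp["x"], grp["y"], s=8, alpha=0.6, label=str(subtype))
    ax.scatter(corners[:, 0], corners[:, 1], c="black", marker="s", s=60,
               zorder=3)
    for i, (x, y) in enumerate(corners):
        ax.annotate(f"z{i + 1}", (x, y), textcoords="offset points",
                    xytext=(4, 4))
    ax.legend(fontsize=7, markerscale=1.5)
    ax.set_aspect("equal")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
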