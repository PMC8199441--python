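"""Optional figure rendering (clustered heatmaps, stacked bars).

Cosmetics are deliberately minimal; the tabular outputs are the primary
interface and these helpers exist for quick visual inspection.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cluster import Dendrogram

__all__ = ["plot_clustered_heatmap", "plot_stacked_counts"]


def plot_clustered_heatmap(
    matrix: pd.DataFrame,
    row_dendrogram: Dendrogram | None,
    path: str | Path,
    cmap: str = "viridis",
) -> None:
    """Heatmap of a frequency matrix with rows in dendrogram leaf order,
    cell values printed."""
    if row_dendrogram is not None:
        matrix = matrix.loc[row_dendrogram.leaf_order]
    fig, ax = plt.subplots(
        figsize=(1 + 0.6 * matrix.shape[1], 1 + 0.4 * matrix.shape[0])
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            v = matrix.iat[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_stacked_counts(
    counts: pd.DataFrame,
    path: str | Path,
    categories: Sequence[str] | None = None,
) -> None:
    """Stacked bar chart of differential binding counts per subfamily."""
    cats = list(categories) if categories else list(counts.columns)
    fig, ax = plt.subplots(figsize=(1 + 0.8 * counts.shape[0], 3))
    bottom = np.zeros(counts.shape[0])
    for cat in cats:
        vals = counts[cat].to_numpy(dtype=float)
        ax.bar(counts.index, vals, bottom=bottom, label=cat)
        bottom += vals
    ax.set_ylabel("elements")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
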