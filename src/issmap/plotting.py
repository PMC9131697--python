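"""Matplotlib renderings: type-pair heatmaps and density rasters."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .density_profiles import KDELayer  # noqa: E402


def heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "",
            significant: pd.DataFrame | None = None,
            cmap: str = "viridis") -> None:
    """Type x type heatmap; significant pairs get a red outline."""
    fig, ax = plt.subplots(figsize=(0.5 * len(matrix.columns) + 2,
                                    0.5 * len(matrix.index) + 2))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap=cmap)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    if significant is not None:
        sig = significant.reindex(index=matrix.index,
                                  columns=matrix.columns).to_numpy()
        for i, j in zip(*np.nonzero(sig == True)):  # noqa: E712
            ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                                       edgecolor="red", linewidth=1.5))
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def density_panel(layers: Mapping[str, KDELayer], path: str | Path,
                  title: str = "") -> None:
    """One panel per type, shared color scale (normalized sections)."""
    names = list(layers)
    ncol = min(4, len(names))
    nrow = -(-len(names) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow),
                             squeeze=False)
    vmax = max(layer.values.max() for layer in layers.values()) or 1.0
    for ax, name in zip(axes.ravel(), names):
        layer = layers[name]
        ax.imshow(layer.values, origin="lower", vmin=0, vmax=vmax,
                  extent=(layer.x[0], layer.x[-1], layer.y[0], layer.y[-1]),
                  cmap="magma")
        ax.set_title(name, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    for ax in axes.ravel()[len(names):]:
        ax.axis("off")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
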