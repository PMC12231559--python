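"""Minimal plotting: adjacency/agreement heatmaps.

A matrix heatmap stands in for 3-D cortical renderings; combine with
:func:`brainlayers.mlnet.threshold_top_fraction` to display only the
strongest links.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_adjacency(
    weights: np.ndarray,
    labels: list[str] | None = None,
    title: str = "",
    out: str | Path | None = None,
):
    """Heatmap of a symmetric adjacency (or agreement) matrix.

    Returns the matplotlib Figure; saves to *out* if given.
    """
    W = np.asarray(weights, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(W, cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="link weight")
    if labels is not None and len(labels) <= 40:
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90, fontsize=5)
        ax.set_yticks(range(len(labels)))
        ax.set_yticklabels(labels, fontsize=5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
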