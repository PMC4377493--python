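"""Score curves and difference-matrix heatmaps."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_score_curves", "plot_difference_matrix"]


def plot_score_curves(scores: pd.DataFrame, ax=None):
    """Mean feedback score per training day, one line per group.

    ``scores`` has a ``day`` column plus one column per group.
    """
    if ax is None:
        _fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for column in scores.columns:
        if column == "day":
            continue
        ax.plot(scores["day"], scores[column], marker="o", label=column)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("training day")
    ax.set_ylabel("mean feedback score")
    ax.set_xticks(scores["day"])
    ax.legend(frameon=False)
    return ax


def plot_difference_matrix(dz: pd.DataFrame, threshold: float | None = None,
                           ax=None, vlim: float = 0.4):
    """Heatmap of a post-minus-pre Fisher-z difference matrix.

    Cells above ``threshold`` (the pooled mean + SD colored-cell rule) are
    outlined.
    """
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 4.5))
    values = dz.to_numpy(dtype=float)
    im = ax.imshow(values, cmap="RdBu_r", vmin=-vlim, vmax=vlim)
    names = list(dz.index)
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    if threshold is not None:
        hits = np.argwhere(values > threshold)
        for i, j in hits:
            if i != j:
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1,
                                           fill=False, edgecolor="k", lw=1.2))
    plt.colorbar(im, ax=ax, label="$\\Delta z$")
    return ax
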