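"""Static plots of state centroids and temporal-metric distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .windows import vec_to_matrix  # noqa: E402


def plot_centroids(centroids: np.ndarray, network_labels: list[str],
                   path=None):
    """Heatmaps of each state centroid as a symmetric z-matrix."""
    k = len(centroids)
    n = len(network_labels)
    fig, axes = plt.subplots(1, k, figsize=(4 * k, 4), squeeze=False)
    vmax = np.abs(centroids).max() or 1.0
    for s in range(k):
        ax = axes[0, s]
        m = vec_to_matrix(centroids[s], n)
        im = ax.imshow(m, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_title(f"State {s + 1}")
        ax.set_xticks(range(n), network_labels, rotation=90, fontsize=6)
        ax.set_yticks(range(n), network_labels, fontsize=6)
    fig.colorbar(im, ax=axes.ravel().tolist(), shrink=0.7, label="Fisher z")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_temporal_violin(temporal, measure: str, path=None):
    """Violin summary of one temporal metric per group."""
    groups = list(dict.fromkeys(temporal["group"]))
    data = [temporal.loc[temporal["group"] == g, measure].to_numpy()
            for g in groups]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_ylabel(measure)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
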