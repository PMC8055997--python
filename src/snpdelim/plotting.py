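"""Optional matplotlib figures: latent scatter with SD circles, delta-K curve.

Imported lazily; the core package does not require matplotlib.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from snpdelim.admixture import EvannoTable
from snpdelim.vae import LatentEmbedding

__all__ = ["plot_latent", "plot_delta_k"]


def plot_latent(
    embedding: LatentEmbedding,
    sample_labels: dict[str, int] | None = None,
    path: str | Path | None = None,
    ax=None,
):
    """Latent scatter: two haplotype points per sample, SD circle per sample.

    Haplotype means are drawn as filled circles (coloured by cluster label
    when given), sample mean positions as black-outlined circles, and each
    sample's SD radius as a translucent circle.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    means = embedding.sample_means()
    radii = embedding.sample_radii()
    labels = [
        (sample_labels or {}).get(s, 0) for s in embedding.sample_ids
    ]
    cmap = plt.get_cmap("tab10")
    for i, sid in enumerate(embedding.sample_ids):
        color = cmap(labels[i] % 10)
        ax.add_patch(Circle(means[i], radii[i], color=color, alpha=0.15, lw=0))
        rows = np.nonzero(embedding.hap_sample_map == i)[0]
        ax.scatter(embedding.mu[rows, 0], embedding.mu[rows, 1],
                   s=18, color=color, zorder=3)
        ax.scatter(*means[i], s=30, facecolor=color, edgecolor="black",
                   linewidth=0.8, zorder=4)
    ax.set_xlabel("latent 1")
    ax.set_ylabel("latent 2")
    ax.set_aspect("equal")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax


def plot_delta_k(table: EvannoTable, path: str | Path | None = None, ax=None):
    """The delta-K curve over interior K with the optimum marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ks = sorted(table.delta_K)
    ax.plot(ks, [table.delta_K[k] for k in ks], marker="o")
    ax.axvline(table.optimal_K, ls="--", color="grey", lw=1)
    ax.set_xlabel("K")
    ax.set_ylabel(r"$\Delta K$")
    ax.set_xticks(ks)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
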