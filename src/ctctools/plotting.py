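"""Optional figures: clustered heatmap, embedding scatter, KM curves.

Matplotlib only; nothing here is required by the analysis path.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .heterogeneity import ClusteringResult, EmbeddingResult
from .matrix import ExpressionMatrix
from .survival import KMEstimate


def heatmap(z: ExpressionMatrix, clustering: ClusteringResult, ax=None):
    """Z-score heatmap with cells ordered by the dendrogram leaves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ordered = z.values[clustering.leaf_order]
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdYlGn_r")
    ax.set_yticks(range(len(ordered.index)), ordered.index, fontsize=6)
    ax.set_xlabel("cells (dendrogram order)")
    ax.figure.colorbar(im, ax=ax, label="Z-score")
    return ax


def embedding_scatter(emb: EmbeddingResult, labels: Sequence[str] | None = None,
                      ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xy = emb.coordinates[:, :2]
    if labels is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=12)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            sel = labels == lab
            ax.scatter(xy[sel, 0], xy[sel, 1], s=12, label=str(lab))
        ax.legend(fontsize=7)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    return ax


def km_curve(est: KMEstimate, label: str | None = None, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(est.timeline, est.survival, where="post", label=label)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("S(t)")
    if label:
        ax.legend()
    return ax
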