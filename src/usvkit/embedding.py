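"""2-D t-SNE projection of the feature space with labeled scatter plots.

t-SNE is used purely as an unsupervised visualization: class labels play no
part in the embedding and only color the resulting scatter plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.manifold import TSNE


@dataclass
class Embedding:
    coords: np.ndarray
    perplexity: float
    seed: int
    feature_subset: list[str] | None = None


def tsne_project(
    X: np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
) -> Embedding:
    """Project samples to 2-D by t-SNE (PCA initialisation, fixed seed)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large: need n > 3*perplexity "
            f"(= {3 * perplexity:.0f}), got n = {n}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        max_iter=n_iter,
        random_state=seed,
    )
    coords = tsne.fit_transform(X)
    if not np.isfinite(coords).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return Embedding(coords=coords, perplexity=perplexity, seed=seed)


def scatter_plot(embedding: Embedding, labels, out_path: str | Path) -> Path:
    """Render the embedding with one marker style/color per call type."""
    coords = embedding.coords
    if len(coords) == 0:
        raise ValueError("cannot plot an empty embedding")
    labels = list(labels)
    if len(labels) != len(coords):
        raise ValueError("labels must align with embedding coordinates")
    classes = sorted(set(labels))
    markers = ["o", "s", "^", "v", "D", "P", "X", "*", "<", ">"]
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(7, 6))
    lab_arr = np.array(labels)
    for i, c in enumerate(classes):
        m = lab_arr == c
        ax.scatter(
            coords[m, 0],
            coords[m, 1],
            s=22,
            marker=markers[i % len(markers)],
            color=cmap(i % 10),
            label=c,
            alpha=0.85,
        )
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
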