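"""Patient-similarity retrieval and 2-D embedding visualization.

Retrieval is exact brute-force cosine search over the stored training-set
embeddings — at desk scale an n × d matrix product beats any approximate
index. Cosine is the natural metric here because the contrastive
pretraining geometry is defined on cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EmbeddingIndex", "query_topk", "hit_score", "tsne_project", "plot_embedding"]


@dataclass
class EmbeddingIndex:
    """n stored embeddings with parallel visit ids and optional labels."""

    embeddings: np.ndarray          # (n, d_hidden)
    visit_ids: list[str]
    labels: list | None = None

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        if self.embeddings.ndim != 2 or len(self.visit_ids) != self.embeddings.shape[0]:
            raise ValueError("row count must equal id count")
        norms = np.linalg.norm(self.embeddings, axis=1)
        if (norms == 0).any():
            raise ValueError("ZERO_VECTOR: index contains zero-norm embeddings")

    def __len__(self) -> int:
        return self.embeddings.shape[0]


def query_topk(index: EmbeddingIndex, q: np.ndarray, k: int = 5
               ) -> list[tuple[str, float]]:
    """The k stored visits most cosine-similar to q, descending similarity;
    ties broken by ascending visit_id for determinism."""
    if len(index) == 0:
        raise ValueError("empty index")
    q = np.asarray(q, dtype=float).reshape(-1)
    qn = np.linalg.norm(q)
    if qn == 0:
        raise ValueError("ZERO_VECTOR: query has zero norm")
    if k > len(index):
        raise ValueError(f"k={k} exceeds index size {len(index)}")
    sims = index.embeddings @ q / (np.linalg.norm(index.embeddings, axis=1) * qn)
    order = sorted(range(len(index)), key=lambda i: (-sims[i], index.visit_ids[i]))
    return [(index.visit_ids[i], float(sims[i])) for i in order[:k]]


def hit_score(retrieved_labels: list, query_label) -> int:
    """0–5 count of top-5 retrieved items sharing the query's label — the
    label-based surrogate for a clinician's relevance judgment of the top-5
    results."""
    if len(retrieved_labels) != 5:
        raise ValueError("hit_score expects exactly 5 retrieved labels")
    return int(sum(1 for lab in retrieved_labels if lab == query_label))


def tsne_project(embeddings: np.ndarray, seed: int = 0,
                 perplexity: float = 30.0) -> np.ndarray:
    """Seeded t-SNE reduction of the embeddings to two dimensions."""
    from sklearn.manifold import TSNE

    embeddings = np.asarray(embeddings, dtype=float)
    n = embeddings.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points for t-SNE")
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca", n_jobs=1)
    return tsne.fit_transform(embeddings)


def plot_embedding(coords: np.ndarray, color_by: np.ndarray, path,
                   title: str = "", categorical: bool | None = None):
    """Scatter the 2-D coordinates colored by a per-visit attribute
    (gender, age decade, triage level, outcome, ...)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    color_by = np.asarray(color_by)
    fig, ax = plt.subplots(figsize=(6, 5))
    if categorical is None:
        categorical = color_by.dtype.kind in "OUSb" or len(np.unique(color_by)) <= 12
    if categorical:
        for value in np.unique(color_by):
            sel = color_by == value
            ax.scatter(coords[sel, 0], coords[sel, 1], s=6, label=str(value), alpha=0.7)
        ax.legend(markerscale=2, fontsize=8)
    else:
        sc = ax.scatter(coords[:, 0], coords[:, 1], s=6, c=color_by, alpha=0.7)
        fig.colorbar(sc, ax=ax)
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
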