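"""2-D embeddings of trace matrices: PCA, t-SNE, UMAP.

PCA delegates to scikit-learn; t-SNE uses the package's exact
implementation (:mod:`catrace.tsne`), which records the per-step KL
divergence; UMAP is consumed from umap-learn as an established algorithm
and degrades gracefully if the import fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from . import tsne as _tsne

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # n × 2, same row order as input
    method: str  # PCA | TSNE | UMAP
    params: dict = field(default_factory=dict)
    objective_trace: np.ndarray | None = None  # per-step KL (t-SNE only)


def embed_pca(matrix: np.ndarray) -> EmbeddingResult:
    """First two principal-component scores of the mean-centered matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 3:
        raise ValueError("PCA embedding requires at least 3 points")
    n_comp = min(2, matrix.shape[0], matrix.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(matrix)
    if n_comp < 2 or pca.explained_variance_[-1] <= 1e-12:
        logger.warning("matrix is rank-deficient; second PCA coordinate zero-filled")
        coords = np.zeros((matrix.shape[0], 2))
        coords[:, :scores.shape[1]] = scores
        if scores.shape[1] == 2 and pca.explained_variance_[1] <= 1e-12:
            coords[:, 1] = 0.0
    else:
        coords = scores
    return EmbeddingResult(coords=coords, method="PCA",
                           params={"n_components": 2})


def embed_tsne(matrix: np.ndarray, perplexity: float = 30.0,
               n_steps: int = 1000, seed: int = 42) -> EmbeddingResult:
    """Exact t-SNE embedding; deterministic given the seed."""
    coords, kl = _tsne.tsne(np.asarray(matrix, dtype=float),
                            perplexity=perplexity, n_steps=n_steps, seed=seed)
    return EmbeddingResult(
        coords=coords, method="TSNE",
        params={"perplexity": perplexity, "n_steps": n_steps, "seed": seed,
                "final_kl": float(kl[-1])},
        objective_trace=kl)


def embed_umap(matrix: np.ndarray, n_neighbors: int = 15,
               min_dist: float = 0.1, seed: int = 42) -> EmbeddingResult | None:
    """UMAP embedding via umap-learn; returns None (with a logged notice) if
    the implementation is unavailable so pipelines can continue."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 10:
        raise ValueError("UMAP embedding requires at least 10 points")
    try:
        import umap
    except Exception as exc:  # pragma: no cover - environment-dependent
        logger.warning("UMAP unavailable (%s); skipping", exc)
        return None
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    coords = reducer.fit_transform(matrix)
    return EmbeddingResult(coords=np.asarray(coords, dtype=float), method="UMAP",
                           params={"n_neighbors": n_neighbors,
                                   "min_dist": min_dist, "seed": seed})
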