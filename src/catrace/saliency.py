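"""Grad-CAM-style per-frame saliency for the feature net, and projection of
all cells (including chaperone-treated ones) into the learned feature space.

Grad-CAM was formulated for convolutional feature maps; a dense network
offers no spatial map to pool over, so the per-frame relevance here is the
class-score sensitivity collapsed onto the input layer:

    r_t = | (∂y_c/∂x)_t |        (default, ``method="gradient"``)

This localizes on the frames the model *relies on* regardless of the raw
signal amplitude there — which is the property the study's saliency claim
is about (the classifier leans on pre-ligand calcium signatures).  Three
variants sit behind the ``method`` flag for comparison: ``grad_x_input``
(ReLU(∂y_c/∂x ⊙ x), the exact per-frame decomposition of the α_k-weighted
active-unit activations Σ_k α_k W1[k,t] x_t, which emphasizes frames with
large signal), ``input_gradient`` (|∂y_c/∂x ⊙ x|), and ``static_weight``
(redistribution by the normalized static magnitudes
ŵ_{k,t} = |W1[k,t]|/Σ_t|W1[k,t]|; near-uniform in practice because Adam
leaves the first-layer magnitude profile flat).  Maps are max-normalized
per cell to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import encode_labels
from .data import TraceMatrix
from .embedding import EmbeddingResult, embed_tsne
from .network import FeatureNet

logger = logging.getLogger(__name__)


@dataclass
class SaliencyMap:
    values: np.ndarray  # cells × frames, each row max-normalized to [0, 1]
    target_class: np.ndarray  # per-cell class index the map explains
    method: str


def _normalize_rows(r: np.ndarray) -> np.ndarray:
    peak = r.max(axis=1, keepdims=True)
    out = np.zeros_like(r)
    nz = peak[:, 0] > 0
    out[nz] = r[nz] / peak[nz]
    return out


def grad_cam_saliency(net: FeatureNet, traces: TraceMatrix | np.ndarray,
                      target_class: np.ndarray | int | None = None,
                      method: str = "gradient") -> SaliencyMap:
    """Per-frame relevance of each cell's trace for its (predicted) class.

    ``target_class`` defaults to the model's predicted class per cell; an int
    applies one class to all cells.  ``method`` is ``gradient`` (default),
    ``grad_x_input``, ``input_gradient``, or ``static_weight`` (see module
    docstring).
    """
    x = traces.values if isinstance(traces, TraceMatrix) else np.asarray(traces, dtype=float)
    n = x.shape[0]
    if target_class is None:
        tc = net.predict(x)
    elif np.isscalar(target_class):
        tc = np.full(n, int(target_class), dtype=int)
    else:
        tc = np.asarray(target_class, dtype=int)

    if method == "gradient":
        rel = np.abs(net.class_input_gradient(x, tc))
    elif method == "grad_x_input":
        grad = net.class_input_gradient(x, tc)
        rel = np.maximum(grad * x, 0.0)
    elif method == "input_gradient":
        grad = net.class_input_gradient(x, tc)
        rel = np.abs(grad * x)
    elif method == "static_weight":
        alpha = net.class_hidden_gradient(x, tc)  # n × hidden1
        a1 = net.hidden_activations(x)
        w_abs = np.abs(net.W1)  # hidden1 × frames
        norms = w_abs.sum(axis=1, keepdims=True)
        w_hat = np.divide(w_abs, norms, out=np.zeros_like(w_abs), where=norms > 0)
        rel = np.maximum((alpha * a1) @ w_hat, 0.0)
    else:
        raise ValueError(f"unknown saliency method {method!r}")

    if not np.any(rel > 0):
        logger.warning("saliency is identically zero (untrained or zero model?)")
    return SaliencyMap(values=_normalize_rows(rel), target_class=tc, method=method)


def localization_score(smap: SaliencyMap, window: tuple[int, int]) -> float:
    """Mean relevance inside [start, end) divided by mean relevance elsewhere."""
    start, end = window
    inside = smap.values[:, start:end].mean()
    mask = np.ones(smap.values.shape[1], dtype=bool)
    mask[start:end] = False
    outside = smap.values[:, mask].mean()
    return float(inside / outside) if outside > 0 else float("inf")


def project_feature_space(net: FeatureNet, traces: TraceMatrix,
                          perplexity: float = 30.0, n_steps: int = 1000,
                          seed: int = 42) -> EmbeddingResult:
    """t-SNE of z2 features of *all* cells, treated cells included.

    The model must be the binary Het/Hom classifier; treated cells are
    passed through it even though they were never seen in training, which is
    exactly the transfer question the feature space is meant to answer.
    """
    if net.config.output_dim != 2:
        raise ValueError("feature-space projection expects the binary HET/HOM model")
    feats = net.features(traces.values)
    result = embed_tsne(feats, perplexity=perplexity, n_steps=n_steps, seed=seed)
    result.params["groups"] = traces.labels.copy()
    return result


def treated_centroid_preference(embedding: EmbeddingResult,
                                labels: np.ndarray) -> dict[str, float]:
    """Mean distance of treated cells to the Het vs Hom centroids in a 2-D map."""
    labels = np.asarray(labels)
    coords = embedding.coords
    out = {}
    for ref in ("HET", "HOM"):
        centroid = coords[labels == ref].mean(axis=0)
        d = np.linalg.norm(coords[labels == "HOM_TREATED"] - centroid, axis=1)
        out[ref] = float(d.mean())
    return out
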