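"""Exact (O(n²)) t-SNE.

Each trace x_i ∈ ℝ^d is compared to every other via a Gaussian kernel whose
bandwidth is calibrated per point to a target perplexity; the conditional
similarities p_{j|i} are symmetrized to p_ij, and a 2-D map is found by
gradient descent on KL(P‖Q) = Σ_{i≠j} p_ij log(p_ij/q_ij), where q_ij uses a
Student-t kernel (one degree of freedom) in the embedding.

The gradient descent uses standard settings: early exaggeration (×4 for the
first 100 steps), momentum 0.5 switching to 0.8 at step 250, learning rate
200.  The per-step KL trace is recorded on the *unexaggerated* P so the
objective is comparable across the whole run.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _pairwise_sq_dists(x: np.ndarray) -> np.ndarray:
    sq = np.sum(x * x, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _conditional_p(d2_row: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """Row of p_{j|i} at precision beta, plus the Shannon entropy (nats)."""
    p = np.exp(-d2_row * beta)
    s = p.sum()
    if s <= 0:
        p = np.full_like(p, 1.0 / max(p.size, 1))
        return p, np.log(max(p.size, 1))
    p /= s
    h = -np.sum(p * np.log(np.maximum(p, _EPS)))
    return p, h


def joint_probabilities(x: np.ndarray, perplexity: float,
                        tol: float = 1e-5, max_iter: int = 64) -> np.ndarray:
    """Symmetrized similarity matrix P with per-point perplexity calibration.

    The per-point Gaussian bandwidth is found by binary search so that the
    entropy of p_{·|i} equals log(perplexity).
    """
    n = x.shape[0]
    d2 = _pairwise_sq_dists(x)
    target_h = np.log(perplexity)
    cond = np.zeros((n, n))
    for i in range(n):
        idx = np.arange(n) != i
        row = d2[i, idx]
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        p, h = _conditional_p(row, beta)
        for _ in range(max_iter):
            if abs(h - target_h) < tol:
                break
            if h > target_h:  # too flat → increase precision
                beta_lo = beta
                beta = beta * 2.0 if np.isinf(beta_hi) else 0.5 * (beta_lo + beta_hi)
            else:
                beta_hi = beta
                beta = 0.5 * (beta_lo + beta_hi)
            p, h = _conditional_p(row, beta)
        cond[i, idx] = p
    p_joint = (cond + cond.T) / (2.0 * n)
    return np.maximum(p_joint, _EPS)


def _q_matrix(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    num = 1.0 / (1.0 + _pairwise_sq_dists(y))
    np.fill_diagonal(num, 0.0)
    q = num / max(num.sum(), _EPS)
    return np.maximum(q, _EPS), num


def kl_divergence(p: np.ndarray, y: np.ndarray) -> float:
    q, _ = _q_matrix(y)
    mask = ~np.eye(p.shape[0], dtype=bool)
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def tsne(x: np.ndarray, perplexity: float = 30.0, n_steps: int = 1000,
         seed: int = 42, learning_rate: float = 200.0,
         early_exaggeration: float = 4.0, exaggeration_steps: int = 100,
         record_every: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Embed ``x`` into 2-D; returns (coords, per-recorded-step KL values).

    Deterministic given ``seed``.  If the point count is too small for the
    requested perplexity it is reduced (with a logged warning) so that
    n > 3·perplexity.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 5:
        raise ValueError("t-SNE requires at least 5 points")
    if n <= 3 * perplexity:
        new_perp = max((n - 1) / 3.0, 2.0)
        logger.warning("perplexity %.1f too large for %d points; reducing to %.1f",
                       perplexity, n, new_perp)
        perplexity = new_perp

    p = joint_probabilities(x, perplexity)
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, 1e-4, size=(n, 2))
    update = np.zeros_like(y)
    gains = np.ones_like(y)
    kl_trace = []

    for step in range(n_steps):
        p_eff = p * early_exaggeration if step < exaggeration_steps else p
        q, num = _q_matrix(y)
        # grad_i = 4 Σ_j (p_ij − q_ij) num_ij (y_i − y_j)
        pq = (p_eff - q) * num
        grad = 4.0 * ((np.diag(pq.sum(axis=1)) - pq) @ y)
        momentum = 0.5 if step < 250 else 0.8
        gains = np.where(np.sign(grad) != np.sign(update),
                         gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        update = momentum * update - learning_rate * gains * grad
        y = y + update
        y = y - y.mean(axis=0)
        if step % record_every == 0 or step == n_steps - 1:
            mask = ~np.eye(n, dtype=bool)
            kl_trace.append(float(np.sum(p[mask] * np.log(p[mask] / q[mask]))))
    return y, np.asarray(kl_trace)
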