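"""Comparator clustering methods and gap-statistic selection of K.

These are the baselines the assisted method is evaluated against: K-means on
the gene columns, spectral clustering of the inverse-distance similarity
graph, K-means on the stacked expression+regulator columns ("augmented"), and
the oracle variant of the assisted method that uses the true coefficient
matrix in place of the estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .anneal import SAConfig, anneal
from .graph import rescale_similarity, similarity_matrix

__all__ = ["kmeans_genes", "spectral_genes", "augmented_kmeans",
           "oracle_ancut", "gap_select_k"]


def _cols(M):
    """Feature columns as points: (p, n) array."""
    M = M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float)
    return M.T


def kmeans_genes(Y, K: int, seed=None, n_restarts: int = 25) -> np.ndarray:
    """K-means on the p gene columns as points in sample space."""
    pts = _cols(Y)
    if pts.shape[0] < K:
        raise ValueError("fewer genes than clusters")
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    return km.fit(pts).labels_


def spectral_genes(W, K: int, seed=None, n_restarts: int = 25) -> np.ndarray:
    """Spectral clustering of a precomputed similarity matrix.

    Symmetric normalized Laplacian, K leading eigenvectors of
    D^{-1/2} W D^{-1/2} (dense decomposition), rows normalized to unit
    length, then K-means in the embedding.
    """
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    deg = W.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    M = inv_sqrt[:, None] * W * inv_sqrt[None, :]
    _, vecs = eigh(M, subset_by_index=(p - K, p - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    emb = vecs / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    return km.fit(emb).labels_


def augmented_kmeans(Y, X, K: int, seed=None, n_restarts: int = 25) -> np.ndarray:
    """K-means on the stacked (expression, regulator) feature columns;
    only the labels of the p genes are returned (some of the K clusters may
    end up without any gene member — the metrics are label-agnostic)."""
    gene_pts = _cols(Y)
    reg_pts = _cols(X)
    if gene_pts.shape[1] != reg_pts.shape[1]:
        raise ValueError("expression and regulators must share samples")
    pts = np.vstack([gene_pts, reg_pts])
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    return km.fit(pts).labels_[: gene_pts.shape[0]]


def oracle_ancut(Y, X, beta_true, cfg: SAConfig, rescale: bool = True) -> np.ndarray:
    """Assisted clustering with the true coefficient matrix (no estimation):
    the denominator similarities come from X beta_true'."""
    Yv = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, dtype=float)
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    W = similarity_matrix(Yv)
    W_hat = similarity_matrix(Xv @ beta_true.T)
    if rescale:
        W = rescale_similarity(W)
        W_hat = rescale_similarity(W_hat)
    labels, _ = anneal(W, W_hat, cfg)
    return labels


def _pooled_dispersion(pts, labels, K):
    """log of the pooled within-cluster dispersion W_K of the gap statistic."""
    total = 0.0
    for k in range(K):
        members = pts[labels == k]
        if len(members) < 2:
            continue
        center = members.mean(axis=0)
        total += ((members - center) ** 2).sum()
    return np.log(max(total, np.finfo(float).tiny))


def gap_select_k(Y, k_max: int, n_ref: int = 10, seed=None,
                 n_restarts: int = 25) -> int:
    """Gap-statistic choice of the cluster count for the gene columns.

    Compares log within-cluster dispersion of K-means solutions against
    uniform draws from the bounding box of the points and returns the
    smallest K with gap(K) >= gap(K+1) - s_{K+1} (one-standard-error rule).
    """
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    pts = _cols(Y)
    rng = np.random.default_rng(seed)
    lo, hi = pts.min(axis=0), pts.max(axis=0)

    def disp(points, K):
        if K == 1:
            labels = np.zeros(len(points), dtype=int)
        else:
            labels = KMeans(n_clusters=K, n_init=n_restarts,
                            random_state=seed).fit(points).labels_
        return _pooled_dispersion(points, labels, K)

    gaps = np.empty(k_max)
    sks = np.empty(k_max)
    refs = [rng.uniform(lo, hi, size=pts.shape) for _ in range(n_ref)]
    for K in range(1, k_max + 1):
        log_wk = disp(pts, K)
        ref_logs = np.array([disp(r, K) for r in refs])
        gaps[K - 1] = ref_logs.mean() - log_wk
        sks[K - 1] = ref_logs.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_ref)
    for K in range(1, k_max):
        if gaps[K - 1] >= gaps[K] - sks[K]:
            return K
    return k_max
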