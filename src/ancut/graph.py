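"""Gene-gene similarity matrices and the (assisted) normalized-cut objectives.

Similarity between two genes is the inverse of the Euclidean distance between
their expression profiles across samples.  The assisted objective divides
cross-cluster similarity mass computed from observed expression (W) by
within-cluster mass computed from the regulator-predicted component (What):

    ANCut(A_1..A_K) = sum_k cut(A_k, A_k^c; W) / cutvol(A_k; What)

where cut sums w_jl over ordered pairs (j in A_k, l outside) and cutvol sums
what_jl over ordered within-cluster pairs.  NCut is the special case
What = W.  Minimizing over partitions favors clusters that are loosely tied
to the rest in observed expression yet dense in the regulated component.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DegenerateSimilarityError",
    "similarity_matrix",
    "rescale_similarity",
    "cut_value",
    "cutvol_value",
    "ancut_objective",
    "ncut_objective",
    "exhaustive_minimizer",
]


class DegenerateSimilarityError(ValueError):
    """Raised when every pairwise distance is zero (all features identical)."""


def similarity_matrix(M, metric: str = "euclidean", zero_cap_scale: float = 1e-12):
    """Inverse-distance similarity between the feature columns of ``M``.

    Parameters
    ----------
    M : array-like of shape (n_samples, p_features)
        Matrix whose columns are compared.
    metric : str
        Only ``"euclidean"`` is supported.
    zero_cap_scale : float
        Pairs at exactly zero distance (duplicate columns) receive the finite
        similarity ``1 / (zero_cap_scale * median positive distance)`` instead
        of an infinity.

    Returns
    -------
    ndarray of shape (p, p)
        Symmetric, non-negative, zero diagonal.
    """
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a 2-d matrix with at least two feature columns")
    D = squareform(pdist(M.T, metric="euclidean"))
    off = ~np.eye(D.shape[0], dtype=bool)
    positive = D[off] > 0
    if not positive.any():
        raise DegenerateSimilarityError(
            "degenerate similarity: all pairwise distances are zero"
        )
    floor = zero_cap_scale * np.median(D[off][positive])
    W = np.zeros_like(D)
    W[off] = 1.0 / np.maximum(D[off], floor)
    return W


def rescale_similarity(W: np.ndarray) -> np.ndarray:
    """Scale ``W`` so its mean off-diagonal entry is one.

    The minimizing partition of either objective is unchanged; only the
    reported objective value becomes comparable across similarity matrices
    built from components of different scale (the predicted component's scale
    depends on the amount of shrinkage).
    """
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    mean = W.sum() / (p * (p - 1))
    if mean <= 0:
        raise DegenerateSimilarityError("similarity matrix has no positive mass")
    return W / mean


def cut_value(labels, k: int, W: np.ndarray) -> float:
    """Similarity mass over ordered pairs (j in cluster k, l outside)."""
    labels = np.asarray(labels)
    inside = labels == k
    return float(W[np.ix_(inside, ~inside)].sum())


def cutvol_value(labels, k: int, W_hat: np.ndarray) -> float:
    """Similarity mass over ordered within-cluster pairs of cluster k.

    The zero diagonal means only off-diagonal pairs contribute; each unordered
    pair is counted twice, matching the double index of the definition.
    """
    labels = np.asarray(labels)
    inside = labels == k
    return float(W_hat[np.ix_(inside, inside)].sum())


def ancut_objective(labels, W: np.ndarray, W_hat: np.ndarray) -> float:
    """Assisted normalized cut of a partition; +inf when any cluster has zero
    within-mass in ``W_hat`` (0/0 included), so such partitions are never
    preferred."""
    W = np.asarray(W, dtype=float)
    W_hat = np.asarray(W_hat, dtype=float)
    if W.shape != W_hat.shape or W.shape[0] != W.shape[1]:
        raise ValueError("W and W_hat must be square matrices of equal size")
    labels = np.asarray(labels)
    if labels.shape[0] != W.shape[0]:
        raise ValueError("labels length must match matrix dimension")
    total = 0.0
    for k in np.unique(labels):
        cut = cut_value(labels, k, W)
        vol = cutvol_value(labels, k, W_hat)
        if vol == 0.0:
            return np.inf  # division policy: x/0 and 0/0 are both +inf
        total += cut / vol
    return total


def ncut_objective(labels, W: np.ndarray) -> float:
    """Classical normalized cut: observed similarities in both roles."""
    return ancut_objective(labels, W, W)


def _partitions_into_k(p: int, K: int):
    """Yield all label vectors partitioning ``p`` items into exactly ``K``
    non-empty blocks, in restricted-growth (lexicographic) order."""
    labels = np.zeros(p, dtype=int)

    def rec(i: int, used: int):
        if i == p:
            if used == K:
                yield labels.copy()
            return
        # pruning: remaining items must be able to open the missing blocks
        if used + (p - i) < K:
            return
        for c in range(min(used + 1, K)):
            labels[i] = c
            yield from rec(i + 1, used + (c == used))

    yield from rec(1, 1)  # item 0 fixed in block 0 (canonical form)


def exhaustive_minimizer(W: np.ndarray, W_hat: np.ndarray, K: int):
    """Global minimizer of the assisted objective by enumerating all
    partitions into ``K`` non-empty clusters.  Test oracle; guarded to small p.

    Returns
    -------
    (labels, value)
        The first (lexicographically smallest canonical label vector)
        global minimizer and its objective value.
    """
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    if p > 14:
        raise ValueError("exhaustive enumeration is limited to p <= 14")
    if not 1 <= K <= p:
        raise ValueError("K must be between 1 and p")
    best_labels, best_value = None, np.inf
    for labels in _partitions_into_k(p, K):
        value = ancut_objective(labels, W, W_hat)
        if value < best_value:
            best_labels, best_value = labels, value
    if best_labels is None:  # every partition is +inf; return the first one
        best_labels = next(_partitions_into_k(p, K))
        best_value = np.inf
    return best_labels, best_value
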