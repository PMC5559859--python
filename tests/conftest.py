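import numpy as np
import pytest

from ancut.graph import similarity_matrix


@pytest.fixture
def four_gene_matrix():
    """Two samples, four genes at columns (0,0), (0,1), (3,0), (3,1).

    Hand-computed pairwise distances: d12 = d34 = 1, d13 = d24 = 3,
    d14 = d23 = sqrt(10).
    """
    return np.array([[0.0, 0.0, 3.0, 3.0],
                     [0.0, 1.0, 0.0, 1.0]])


@pytest.fixture
def four_gene_similarity(four_gene_matrix):
    return similarity_matrix(four_gene_matrix)


def brute_force_cut(labels, k, W):
    """Independent double-loop oracle for the cross-cluster mass."""
    labels = np.asarray(labels)
    total = 0.0
    p = len(labels)
    for j in range(p):
        for l in range(p):
            if labels[j] == k and labels[l] != k:
                total += W[j, l]
    return total


def brute_force_cutvol(labels, k, W):
    labels = np.asarray(labels)
    total = 0.0
    p = len(labels)
    for j in range(p):
        for l in range(p):
            if labels[j] == k and labels[l] == k:
                total += W[j, l]
    return total


def brute_force_objective(labels, W, W_hat):
    labels = np.asarray(labels)
    total = 0.0
    for k in np.unique(labels):
        vol = brute_force_cutvol(labels, k, W_hat)
        if vol == 0.0:
            return np.inf
        total += brute_force_cut(labels, k, W) / vol
    return total
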