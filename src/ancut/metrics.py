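"""Label-invariant accuracy and stability measures for clusterings.

Both are built on the binary co-clustering (adjacency) matrix A with
a_jl = 1 when genes j and l share a cluster (diagonal 1).  Accuracy is the
normalized disagreement between the adjacency matrices of the true and
estimated partitions, sum |A_T - A_hat| / p^2: zero at perfect recovery, and
invariant to relabeling either partition.  Stability is the mean pairwise
disagreement across replicate clusterings (a U-statistic); for two replicates
it coincides with the accuracy measure applied to the pair.
"""

from __future__ import annotations

import numpy as np

__all__ = ["adjacency_matrix", "accuracy_measure", "stability_measure",
           "adjacency_product_score"]


def adjacency_matrix(labels) -> np.ndarray:
    """Binary co-membership matrix of a partition (diagonal all ones)."""
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(float)


def accuracy_measure(true_labels, est_labels) -> float:
    """Normalized adjacency disagreement in [0, 1]; 0 = perfect recovery."""
    true_labels = np.asarray(true_labels)
    est_labels = np.asarray(est_labels)
    if true_labels.shape != est_labels.shape:
        raise ValueError("partitions must cover the same number of genes")
    p = true_labels.shape[0]
    diff = np.abs(adjacency_matrix(true_labels) - adjacency_matrix(est_labels))
    return float(diff.sum() / p**2)


def stability_measure(label_sets) -> float:
    """Mean pairwise adjacency disagreement over N >= 2 replicate
    clusterings."""
    label_sets = [np.asarray(ls) for ls in label_sets]
    n = len(label_sets)
    if n < 2:
        raise ValueError("stability requires at least two replicates")
    p = label_sets[0].shape[0]
    if any(ls.shape != (p,) for ls in label_sets):
        raise ValueError("all replicates must cover the same genes")
    adjacency = [adjacency_matrix(ls) for ls in label_sets]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.abs(adjacency[i] - adjacency[j]).sum() / p**2
    return float(total / (n * (n - 1) / 2))


def adjacency_product_score(true_labels, est_labels) -> float:
    """Component-wise-product form sum (A_T * A_hat) / p^2.

    Debug helper only: this agreement-style score is 0.5 at perfect recovery
    of two equal clusters and does not order results the way the
    disagreement measure does.
    """
    prod = adjacency_matrix(true_labels) * adjacency_matrix(est_labels)
    return float(prod.sum() / len(np.asarray(true_labels)) ** 2)
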