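"""Replicated simulation experiments comparing clustering methods.

One experiment cell = one :class:`~ancut.simulate.SimulationConfig` plus a
set of methods.  Replicate r uses seed ``base_seed + r``, and all methods
within a replicate consume the identical simulated dataset (paired design).
Accuracy is computed per replicate against the planted partition; stability
is the mean pairwise adjacency disagreement across the replicate clusterings
of each method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .anneal import SAConfig
from .cluster import ANCut, NCut
from .compare import augmented_kmeans, kmeans_genes, oracle_ancut, spectral_genes
from .metrics import accuracy_measure, stability_measure
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["run_simulation_experiment", "METHODS"]

METHODS = ("ancut", "ancut_true", "ncut", "kmeans", "spectral", "augk")


def _run_replicate(config: SimulationConfig, methods, B, L, alpha_grid,
                   n_lambda, n_folds, n_restarts, seed):
    data = simulate_dataset(config.with_seed(seed))
    Y, X = data.Y, data.X
    out = {}
    for method in methods:
        if method == "ancut":
            est = ANCut(n_clusters=2, n_iter=B, L=L, alpha_grid=alpha_grid,
                        n_lambda=n_lambda, n_folds=n_folds, random_state=seed)
            out[method] = est.fit(Y, regulators=X).labels_
        elif method == "ancut_true":
            cfg = SAConfig(K=2, B=B, L=L, seed=seed)
            out[method] = oracle_ancut(Y, X, data.beta_true, cfg)
        elif method == "ncut":
            est = NCut(n_clusters=2, n_iter=B, L=L, random_state=seed)
            out[method] = est.fit(Y).labels_
        elif method == "kmeans":
            out[method] = kmeans_genes(Y, 2, seed=seed, n_restarts=n_restarts)
        elif method == "spectral":
            from .graph import similarity_matrix
            W = similarity_matrix(Y.to_numpy())
            out[method] = spectral_genes(W, 2, seed=seed,
                                         n_restarts=n_restarts)
        elif method == "augk":
            out[method] = augmented_kmeans(Y, X, 2, seed=seed,
                                           n_restarts=n_restarts)
        else:
            raise ValueError(f"unknown method {method!r}")
    accuracy = {m: accuracy_measure(data.true_labels, lab)
                for m, lab in out.items()}
    return out, accuracy


def run_simulation_experiment(config: SimulationConfig, methods=METHODS,
                              n_reps: int = 100, base_seed: int = 0,
                              B: int = 10_000, L: float = 1000.0,
                              alpha_grid=(0.5,), n_lambda: int = 100,
                              n_folds: int = 5, n_restarts: int = 25,
                              n_jobs: int = 1):
    """Run ``n_reps`` paired replicates of one simulation cell.

    Returns
    -------
    summary : DataFrame indexed by method with columns
        (mean_accuracy, se_accuracy, stability, n_reps)
    accuracy : DataFrame of per-replicate accuracy values (rows = replicates)
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    seeds = [base_seed + r for r in range(n_reps)]
    results = Parallel(n_jobs=n_jobs)(
        delayed(_run_replicate)(config, methods, B, L, alpha_grid, n_lambda,
                                n_folds, n_restarts, s)
        for s in seeds)
    labels = {m: [res[0][m] for res in results] for m in methods}
    acc = pd.DataFrame({m: [res[1][m] for res in results] for m in methods})
    rows = []
    for m in methods:
        stab = (stability_measure(labels[m]) if n_reps >= 2 else np.nan)
        rows.append({
            "method": m,
            "mean_accuracy": acc[m].mean(),
            "se_accuracy": acc[m].std(ddof=1) / np.sqrt(n_reps)
            if n_reps > 1 else np.nan,
            "stability": stab,
            "n_reps": n_reps,
        })
    summary = pd.DataFrame(rows).set_index("method")
    return summary, acc
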