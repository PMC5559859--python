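"""Assisted and plain normalized-cut clustering estimators.

``ANCut`` runs the full assisted pipeline: elastic-net regression of
expression on regulators, similarity matrices from the observed expression
(numerator) and the predicted regulated component (denominator), and
simulated annealing over partitions.  ``NCut`` is the unassisted special case
using observed expression in both roles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .anneal import SAConfig, anneal
from .graph import rescale_similarity, similarity_matrix
from .regression import RegulationModel

__all__ = ["ANCut", "NCut"]


def _as_array(M):
    return M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float)


def _seed_from(random_state) -> int:
    if random_state is None:
        return int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    return int(random_state)


class NCut(BaseEstimator, ClusterMixin):
    """Normalized-cut clustering of feature columns by simulated annealing.

    Parameters
    ----------
    n_clusters : int
        Number of clusters K.
    n_iter : int
        Simulated-annealing iteration budget B.
    L : float or "auto"
        Inverse-temperature coefficient; "auto" calibrates it to the typical
        uphill objective delta of the instance.  1000 reproduces the original
        software on unit-rescaled similarities at p ~ 100-500.
    schedule : {"cooling", "printed"}
        ``cooling`` uses T(t) = 1/(L log(t+1)) (inverse temperature
        growing like log t); ``printed`` the increasing L*log(t+1) variant.
    metric : str
        Distance underlying the inverse-distance similarity.
    rescale : bool
        Rescale the similarity matrix to unit mean off-diagonal before
        optimisation (reported objective values only; the optimum partition
        is unaffected).
    random_state : int or None

    Attributes
    ----------
    labels_ : ndarray of shape (p,)
    best_objective_ : float
    objective_trace_ : ndarray of shape (n_iter,)
    n_accepted_ : int
    """

    def __init__(self, n_clusters=2, n_iter=10_000, L="auto",
                 schedule="cooling", metric="euclidean", rescale=True,
                 random_state=None):
        self.n_clusters = n_clusters
        self.n_iter = n_iter
        self.L = L
        self.schedule = schedule
        self.metric = metric
        self.rescale = rescale
        self.random_state = random_state

    def _anneal(self, W, W_hat):
        L = None if self.L == "auto" else self.L
        cfg = SAConfig(K=self.n_clusters, B=self.n_iter, L=L,
                       schedule=self.schedule, seed=_seed_from(self.random_state))
        labels, trace = anneal(W, W_hat, cfg)
        self.labels_ = labels
        self.best_objective_ = trace.best_value
        self.objective_trace_ = trace.objective_sequence
        self.n_accepted_ = trace.accept_count
        return self

    def fit(self, X, y=None):
        """Cluster the feature columns of the expression matrix ``X``."""
        W = similarity_matrix(_as_array(X), metric=self.metric)
        if self.rescale:
            W = rescale_similarity(W)
        self.similarity_ = W
        return self._anneal(W, W)


class ANCut(NCut):
    """Assisted normalized-cut clustering of genes using regulator data.

    The cut numerator uses similarities of observed expression; the
    normalizing denominator uses similarities of the component of expression
    predicted from the regulators by a cross-validated elastic net.

    Parameters (beyond those of ``NCut``)
    ----------
    alpha_grid : tuple of float
        Elastic-net mixing weights searched by cross-validation;
        ``(0.5,)`` reproduces the original software default.
    n_lambda, n_folds, lambda_min_ratio :
        Passed to :class:`~ancut.regression.RegulationModel`.

    Additional attributes
    ---------------------
    regulation_ : RegulationModel
    lambda_, alpha_ : float
        Cross-validation selected penalty parameters.
    """

    def __init__(self, n_clusters=2, n_iter=10_000, L="auto",
                 schedule="cooling", metric="euclidean", rescale=True,
                 alpha_grid=(0.5,), n_lambda=100, n_folds=5,
                 lambda_min_ratio=1e-4, random_state=None):
        super().__init__(n_clusters=n_clusters, n_iter=n_iter, L=L,
                         schedule=schedule, metric=metric, rescale=rescale,
                         random_state=random_state)
        self.alpha_grid = alpha_grid
        self.n_lambda = n_lambda
        self.n_folds = n_folds
        self.lambda_min_ratio = lambda_min_ratio

    def fit(self, X, y=None, *, regulators=None, beta=None):
        """Cluster genes (columns of expression ``X``).

        ``regulators`` is the n x q regulator matrix (may also be passed
        positionally in place of ``y``, mirroring ``fit(Y, X)`` usage).
        If ``beta`` (p x q) is given, the regression step is skipped and the
        predicted component is built directly from it — the "true-beta"
        oracle variant.
        """
        if regulators is None:
            regulators = y
        if regulators is None:
            raise ValueError("ANCut.fit requires the regulator matrix")
        Y = _as_array(X)
        R = _as_array(regulators)
        if Y.shape[0] != R.shape[0]:
            raise ValueError("expression and regulators must share samples")
        if beta is None:
            model = RegulationModel(alpha_grid=self.alpha_grid,
                                    n_lambda=self.n_lambda,
                                    n_folds=self.n_folds,
                                    lambda_min_ratio=self.lambda_min_ratio,
                                    random_state=_seed_from(self.random_state))
            model.fit(R, Y)
            self.regulation_ = model
            self.lambda_ = model.lambda_
            self.alpha_ = model.alpha_
            Y_hat = model.predict(R)
        else:
            beta = np.asarray(beta, dtype=float)
            Y_hat = R @ beta.T
        W = similarity_matrix(Y, metric=self.metric)
        W_hat = similarity_matrix(Y_hat, metric=self.metric)
        if self.rescale:
            W = rescale_similarity(W)
            W_hat = rescale_similarity(W_hat)
        self.similarity_ = W
        self.similarity_predicted_ = W_hat
        return self._anneal(W, W_hat)

    def fit_predict(self, X, y=None, **kwargs):
        """Fit and return cluster labels (``y`` carries the regulators)."""
        return self.fit(X, y, **kwargs).labels_

    def predict_component(self, regulators):
        """Regulated expression component for new samples."""
        check_is_fitted(self, "regulation_")
        return self.regulation_.predict(_as_array(regulators))
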