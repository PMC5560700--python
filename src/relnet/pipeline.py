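"""End-to-end estimator: counts in, relevance network and error rates out."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .correlation import BayesianCorrelation, GroupedPearsonCorrelation
from .entropy import EntropyFilter
from .network import RelevanceNetwork, build_network
from .permutation import build_null, network_error_estimates, threshold_at_fdr

__all__ = ["BayesianRelevanceNetwork"]


class BayesianRelevanceNetwork(BaseEstimator):
    """The full pipeline as one scikit-learn estimator.

    Optionally removes low-entropy entities, fits the grouped Bayesian (or
    classical Pearson) correlation matrix, builds a pooled permutation null
    with K repetitions, and thresholds the network either at a fixed
    correlation ``threshold`` or at the most permissive threshold whose
    permutation-estimated FDR is at most ``target_fdr``.

    ``X`` is (n_samples, n_entities) raw counts; ``y`` gives the group
    label of each sample.
    """

    def __init__(
        self,
        method: str = "bayesian",
        prior=None,
        include_within_sample_cov: bool = False,
        entropy_filter: bool = False,
        h_thresh_percent: float = 10.0,
        K: int = 100,
        threshold: float | None = None,
        target_fdr: float | None = None,
        random_state=None,
    ):
        self.method = method
        self.prior = prior
        self.include_within_sample_cov = include_within_sample_cov
        self.entropy_filter = entropy_filter
        self.h_thresh_percent = h_thresh_percent
        self.K = K
        self.threshold = threshold
        self.target_fdr = target_fdr
        self.random_state = random_state

    def fit(self, X, y, entity_ids=None):
        X = np.asarray(X, dtype=float)
        if entity_ids is None:
            entity_ids = np.array([f"e{i}" for i in range(X.shape[1])], dtype=object)
        entity_ids = np.asarray(entity_ids, dtype=object)

        if self.entropy_filter:
            self.filter_ = EntropyFilter(self.h_thresh_percent).fit(X, entity_ids=entity_ids)
            support = self.filter_.get_support()
        else:
            self.filter_ = None
            support = np.ones(X.shape[1], dtype=bool)
        self.kept_entities_ = entity_ids[support]
        Xk = X[:, support]

        if self.method == "bayesian":
            model = BayesianCorrelation(
                prior=self.prior,
                include_within_sample_cov=self.include_within_sample_cov,
            )
        elif self.method == "pearson":
            model = GroupedPearsonCorrelation()
        else:
            raise ValueError(f"unknown method {self.method!r}")
        model.fit(Xk, y, entity_ids=self.kept_entities_)
        self.correlation_model_ = model
        self.result_ = model.result_
        self.null_ = build_null(model, K=self.K, random_state=self.random_state)

        self.threshold_ = None
        self.error_estimate_ = None
        self.network_: RelevanceNetwork | None = None
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            self.error_estimate_ = network_error_estimates(
                self.null_, self.result_, self.threshold_
            )
        elif self.target_fdr is not None:
            est = threshold_at_fdr(self.null_, self.result_, self.target_fdr)
            if est is not None:
                self.threshold_ = est.threshold
                self.error_estimate_ = est
        if self.threshold_ is not None:
            self.network_ = build_network(self.result_, self.threshold_)
        return self
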