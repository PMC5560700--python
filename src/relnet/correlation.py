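"""Grouped Bayesian and Pearson correlation estimators.

The Bayesian correlation of two entities is a Pearson-style ratio in which
variances and covariances are taken jointly across groups and across
posterior uncertainty about the latent expression fractions:

    r_ij^B = cov_{g,u}(p_ig, p_jg) / sqrt(var_{g,u}(p_ig) var_{g,u}(p_jg))

Uncertainty from finite sequencing depth inflates the denominator, so
correlations supported only by a handful of reads are moderated toward
zero, while deeply sequenced entities converge to the classical grouped
Pearson correlation of their expression values.

Estimators follow scikit-learn conventions: ``X`` is (n_samples,
n_entities), ``y`` holds the per-sample group labels, and fitted results
live in trailing-underscore attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import CountMatrix, ExpressionMatrix, GroupAssignment, normalize
from .posterior import DirichletPosterior, GroupMoments, group_moments, posterior_from_counts

__all__ = [
    "CorrelationResult",
    "BayesianCorrelation",
    "GroupedPearsonCorrelation",
    "bayesian_correlation_matrix",
    "pearson_group_correlation_matrix",
]


@dataclass
class CorrelationResult:
    """Symmetric matrix of pairwise grouped correlations.

    ``undefined_entities`` marks entities whose total variance is zero;
    every pair touching one is masked (NaN in ``r``), never silently 0.
    The diagonal is 1 by convention and self-pairs are never edges.
    """

    r: np.ndarray
    method: str
    include_within_sample_cov: bool = False
    entity_ids: np.ndarray | None = None
    undefined_entities: np.ndarray = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.undefined_entities is None:
            self.undefined_entities = np.zeros(self.r.shape[0], dtype=bool)
        if self.entity_ids is None:
            self.entity_ids = np.array([f"e{i}" for i in range(self.r.shape[0])], dtype=object)
        else:
            self.entity_ids = np.asarray(self.entity_ids, dtype=object)

    @property
    def n_entities(self) -> int:
        return self.r.shape[0]

    @property
    def pair_mask(self) -> np.ndarray:
        """Boolean (m, m): True where the pair correlation is undefined."""
        u = self.undefined_entities
        return u[:, None] | u[None, :]

    def pairs(self) -> pd.DataFrame:
        """Long-format list of defined pairs i < j with their correlation."""
        m = self.n_entities
        iu, ju = np.triu_indices(m, k=1)
        keep = ~self.pair_mask[iu, ju]
        return pd.DataFrame(
            {
                "entity_i": self.entity_ids[iu[keep]],
                "entity_j": self.entity_ids[ju[keep]],
                "r": self.r[iu[keep], ju[keep]],
            }
        )

    def defined_upper_values(self) -> np.ndarray:
        m = self.n_entities
        iu, ju = np.triu_indices(m, k=1)
        keep = ~self.pair_mask[iu, ju]
        return self.r[iu[keep], ju[keep]]

    def n_defined_pairs(self) -> int:
        return len(self.defined_upper_values())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, index=self.entity_ids, columns=self.entity_ids).to_csv(
            path, sep="\t", index_label="entity_id"
        )

    def pairs_to_tsv(self, path) -> None:
        self.pairs().to_csv(path, sep="\t", index=False)


def _as_arrays(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_entities)")
    y = np.asarray(y)
    if len(y) != X.shape[0]:
        raise ValueError("y must hold one group label per sample")
    labels, codes = np.unique(y, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("at least 2 groups are required for cross-group correlation")
    return X, labels, codes


def _group_reduce(values: np.ndarray, codes: np.ndarray, n: int, how: str) -> np.ndarray:
    """Column-group means or sums of an (m, n_samples) array -> (m, n)."""
    out = np.zeros((values.shape[0], n))
    for g in range(n):
        cols = codes == g
        out[:, g] = values[:, cols].mean(axis=1) if how == "mean" else values[:, cols].sum(axis=1)
    return out


class BayesianCorrelation(BaseEstimator):
    """Uncertainty-moderated grouped correlation of count data.

    Parameters
    ----------
    prior : float, array-like or None
        Symmetric Dirichlet prior weight per entity; ``None`` uses 1/m.
    include_within_sample_cov : bool
        Include the (negative, usually negligible) within-sample belief
        covariance term in the numerator.  Skipping it is the fast path;
        both routes share denominators.

    Attributes
    ----------
    correlation_ : ndarray (m, m)
        Bayesian correlations, unit diagonal, NaN on masked pairs.
    total_variance_ : ndarray (m,)
        Denominator variances var_{g,u}(p_ig).
    posterior_, moments_ : fitted model components.
    """

    def __init__(self, prior=None, include_within_sample_cov: bool = False):
        self.prior = prior
        self.include_within_sample_cov = include_within_sample_cov

    def fit(self, X, y, entity_ids=None):
        X, labels, codes = _as_arrays(X, y)
        counts = X.T  # entities x samples internally
        post = posterior_from_counts(counts, self.prior)
        n = len(labels)
        sizes = np.bincount(codes, minlength=n)
        E, V = post.means, post.variances
        M = _group_reduce(E, codes, n, "mean")
        GV = _group_reduce(V, codes, n, "sum") / sizes[None, :] ** 2
        grand = M.mean(axis=1)
        Mc = M - grand[:, None]
        cross_cov = Mc @ Mc.T / n
        e_var = GV.mean(axis=1)
        tot = np.diag(cross_cov) + e_var

        numer = cross_cov.copy()
        if self.include_within_sample_cov:
            numer += self._within_term(post, codes, sizes, n)
        undefined = tot <= 0.0
        safe = np.where(undefined, 1.0, tot)
        r = numer / np.sqrt(np.outer(safe, safe))
        np.fill_diagonal(r, 1.0)
        r[undefined, :] = np.nan
        r[:, undefined] = np.nan

        self.n_features_in_ = counts.shape[0]
        self.group_labels_ = labels
        self.group_codes_ = codes
        self.group_sizes_ = sizes
        self.posterior_ = post
        self.moments_ = GroupMoments(M, GV, grand, list(labels), sizes, codes)
        self.cross_group_cov_ = cross_cov
        self.uncertainty_variance_ = e_var
        self.total_variance_ = tot
        self.undefined_entities_ = undefined
        self.correlation_ = r
        self.result_ = CorrelationResult(
            r,
            "bayesian",
            self.include_within_sample_cov,
            entity_ids,
            undefined,
        )
        return self

    @staticmethod
    def _within_term(post: DirichletPosterior, codes, sizes, n) -> np.ndarray:
        """E_g(cov_u(p_ig, p_jg)) for all pairs: -(U w) U^T with per-sample
        weights w_s = 1/(n n_g^2).  The diagonal of this matrix is not the
        variance term and is overwritten by the unit-diagonal convention."""
        at = post.alpha_totals
        U = post.alpha / (at * np.sqrt(at + 1.0))
        w = 1.0 / (n * sizes[codes] ** 2)
        return -(U * w) @ U.T

    def within_sample_cov_term(self) -> np.ndarray:
        check_is_fitted(self, "posterior_")
        return self._within_term(
            self.posterior_, self.group_codes_, self.group_sizes_, len(self.group_labels_)
        )


class GroupedPearsonCorrelation(BaseEstimator):
    """Classical baseline: Pearson correlation across groups of the
    within-group mean expression (maximum-likelihood RPM).

    Parameters
    ----------
    normalize_counts : bool
        When True (default) ``X`` holds raw counts and is converted to
        maximum-likelihood RPM per sample; when False ``X`` is already
        depth-normalized expression.
    """

    def __init__(self, normalize_counts: bool = True):
        self.normalize_counts = normalize_counts

    def fit(self, X, y, entity_ids=None):
        X, labels, codes = _as_arrays(X, y)
        values = X.T
        if self.normalize_counts:
            totals = values.sum(axis=0)
            safe = np.where(totals == 0, 1.0, totals)
            values = values / safe * 1e6
            values[:, totals == 0] = 0.0
        n = len(labels)
        M = _group_reduce(values, codes, n, "mean")
        Mc = M - M.mean(axis=1)[:, None]
        cov = Mc @ Mc.T / n  # population (1/n) weighting across groups
        var = np.diag(cov)
        undefined = var <= 0.0
        safe = np.where(undefined, 1.0, var)
        r = cov / np.sqrt(np.outer(safe, safe))
        np.fill_diagonal(r, 1.0)
        r[undefined, :] = np.nan
        r[:, undefined] = np.nan

        self.n_features_in_ = values.shape[0]
        self.group_labels_ = labels
        self.group_codes_ = codes
        self.group_sizes_ = np.bincount(codes, minlength=n)
        self.group_means_ = M
        self.cross_group_cov_ = cov
        self.total_variance_ = var
        self.undefined_entities_ = undefined
        self.correlation_ = r
        self.result_ = CorrelationResult(r, "pearson", False, entity_ids, undefined)
        return self


def bayesian_correlation_matrix(
    post_or_cm,
    groups: GroupAssignment,
    include_within_sample_cov: bool = False,
    prior=None,
) -> CorrelationResult:
    """Functional wrapper over :class:`BayesianCorrelation`.

    Accepts a :class:`CountMatrix` (preferred) or a raw (m, n_samples)
    count array with positional sample ids.
    """
    if isinstance(post_or_cm, CountMatrix):
        counts = post_or_cm.counts
        sample_ids = post_or_cm.sample_ids
        entity_ids = post_or_cm.entity_ids
    else:
        counts = np.asarray(post_or_cm, dtype=float)
        sample_ids = list(range(counts.shape[1]))
        entity_ids = None
    codes = groups.codes(sample_ids)
    labels = [groups.labels[c] for c in codes]
    est = BayesianCorrelation(prior=prior, include_within_sample_cov=include_within_sample_cov)
    est.fit(counts.T, labels, entity_ids=entity_ids)
    return est.result_


def pearson_group_correlation_matrix(
    expr: ExpressionMatrix | CountMatrix, groups: GroupAssignment
) -> CorrelationResult:
    """Functional wrapper over :class:`GroupedPearsonCorrelation`."""
    if isinstance(expr, CountMatrix):
        expr = normalize(expr, "RPM")
    codes = groups.codes(expr.sample_ids)
    labels = [groups.labels[c] for c in codes]
    est = GroupedPearsonCorrelation(normalize_counts=False)
    est.fit(expr.values.T, labels, entity_ids=expr.entity_ids)
    return est.result_
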