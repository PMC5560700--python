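"""Dirichlet posterior beliefs over idealized expression fractions.

Each sample's read counts are modeled as a multinomial draw over the m
entities, with a symmetric Dirichlet prior of weight 1/m per entity on the
latent fractions p_igs.  The posterior for a sample is then
Dirichlet(alpha_1, ..., alpha_m) with alpha_i = 1/m + R_i, and all the
moments needed for grouped Bayesian correlations are available in closed
form: per-sample marginal means and variances, the negative within-sample
covariances induced by the sum-to-one constraint, group-level moments under
belief independence across samples, and total (cross-group plus
uncertainty) variances and covariances via the Laws of Total Variance and
Covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountMatrix, GroupAssignment

__all__ = [
    "DirichletPosterior",
    "GroupMoments",
    "posterior_from_counts",
    "sample_mean",
    "sample_variance",
    "sample_pair_covariance",
    "group_moments",
    "group_pair_covariance",
    "total_variance",
    "total_covariance",
]


@dataclass
class DirichletPosterior:
    """Per-sample Dirichlet posterior parameters alpha_igs.

    ``alpha`` has shape (m, n_samples); ``prior_value`` is the symmetric
    prior weight added to every count (default 1/m), or a per-entity vector.
    """

    alpha: np.ndarray
    prior_value: np.ndarray | float
    entity_ids: np.ndarray | None = None
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha <= 0):
            raise ValueError("posterior parameters must be positive")

    @property
    def alpha_totals(self) -> np.ndarray:
        """Per-sample totals alpha_gs = sum_i alpha_igs."""
        return self.alpha.sum(axis=0)

    @property
    def n_entities(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alpha.shape[1]

    # vectorized marginal moments, shape (m, n_samples)

    @property
    def means(self) -> np.ndarray:
        return self.alpha / self.alpha_totals

    @property
    def variances(self) -> np.ndarray:
        at = self.alpha_totals
        return self.alpha * (at - self.alpha) / (at**2 * (at + 1.0))


def posterior_from_counts(
    cm: CountMatrix | np.ndarray, prior_value: float | np.ndarray | None = None
) -> DirichletPosterior:
    """Posterior alpha = prior + counts; default symmetric prior 1/m.

    The 1/m choice keeps the total prior weight at one pseudo-read per
    sample regardless of how many entities are modeled, which has low bias
    for entities represented by few reads.
    """
    if isinstance(cm, CountMatrix):
        counts, eids, sids = cm.counts, cm.entity_ids, cm.sample_ids
    else:
        counts = np.asarray(cm, dtype=float)
        eids = sids = None
    m = counts.shape[0]
    if prior_value is None:
        prior_value = 1.0 / m
    prior = np.asarray(prior_value, dtype=float)
    if np.any(prior <= 0):
        raise ValueError("prior_value must be positive")
    if prior.ndim == 1:
        alpha = counts + prior[:, None]
    elif prior.ndim == 0:
        alpha = counts + prior
    else:
        raise ValueError("prior_value must be scalar or per-entity vector")
    return DirichletPosterior(alpha, prior_value, eids, sids)


def sample_mean(post: DirichletPosterior, i: int, s: int) -> float:
    """Posterior mean E_u(p_igs) = alpha_igs / alpha_gs."""
    return post.alpha[i, s] / post.alpha_totals[s]


def sample_variance(post: DirichletPosterior, i: int, s: int) -> float:
    """Marginal posterior variance of p_igs."""
    a = post.alpha[i, s]
    at = post.alpha_totals[s]
    return a * (at - a) / (at**2 * (at + 1.0))


def sample_pair_covariance(post: DirichletPosterior, i: int, j: int, s: int) -> float:
    """Within-sample posterior covariance of p_igs and p_jgs (i != j); <= 0."""
    if i == j:
        raise ValueError("i == j: use sample_variance")
    at = post.alpha_totals[s]
    return -post.alpha[i, s] * post.alpha[j, s] / (at**2 * (at + 1.0))


@dataclass
class GroupMoments:
    """Posterior moments of the group-mean fractions p_ig.

    ``group_mean[i, g] = E_u(p_ig)``, ``group_var[i, g] = var_u(p_ig)``,
    ``grand_mean[i] = E_u(p_i)`` with groups weighted equally.
    """

    group_mean: np.ndarray
    group_var: np.ndarray
    grand_mean: np.ndarray
    group_labels: list
    group_sizes: np.ndarray
    codes: np.ndarray  # group index per sample (column of alpha)


def _codes(post: DirichletPosterior, groups: GroupAssignment) -> np.ndarray:
    if post.sample_ids is not None:
        return groups.codes(post.sample_ids)
    # positional fallback for bare arrays: groups must cover range(n_samples)
    return groups.codes(list(range(post.n_samples)))


def group_moments(post: DirichletPosterior, groups: GroupAssignment) -> GroupMoments:
    """Group-level posterior means and variances.

    Beliefs about different samples are independent, so the variance of the
    group mean is the sum of per-sample variances divided by n_g^2.
    """
    codes = _codes(post, groups)
    n = groups.n
    E, V = post.means, post.variances
    m = post.n_entities
    group_mean = np.zeros((m, n))
    group_var = np.zeros((m, n))
    sizes = np.zeros(n, dtype=int)
    for g in range(n):
        cols = codes == g
        ng = int(cols.sum())
        if ng == 0:
            raise ValueError(f"group {groups.labels[g]!r} has no samples")
        sizes[g] = ng
        group_mean[:, g] = E[:, cols].mean(axis=1)
        group_var[:, g] = V[:, cols].sum(axis=1) / ng**2
    grand_mean = group_mean.mean(axis=1)
    return GroupMoments(group_mean, group_var, grand_mean, groups.labels, sizes, codes)


def group_pair_covariance(
    post: DirichletPosterior, groups: GroupAssignment, i: int, j: int, g
) -> float:
    """Posterior covariance of the group means p_ig and p_jg (i != j).

    Only same-sample terms survive (beliefs are independent across
    samples), each divided by n_g^2.
    """
    if i == j:
        raise ValueError("i == j: use group variance")
    codes = _codes(post, groups)
    gi = groups.labels.index(g) if g in groups.labels else int(g)
    cols = np.flatnonzero(codes == gi)
    at = post.alpha_totals[cols]
    cov = -(post.alpha[i, cols] * post.alpha[j, cols] / (at**2 * (at + 1.0))).sum()
    return cov / len(cols) ** 2


def total_variance(moments: GroupMoments, i: int | None = None):
    """Total variance var_{g,u}(p_ig): cross-group spread of posterior
    group means plus the mean posterior group variance (Law of Total
    Variance, groups equally weighted)."""
    dev = moments.group_mean - moments.grand_mean[:, None]
    tv = (dev**2).mean(axis=1) + moments.group_var.mean(axis=1)
    return tv if i is None else float(tv[i])


def total_covariance(
    moments: GroupMoments,
    post: DirichletPosterior,
    i: int,
    j: int,
    include_within_sample_cov: bool = True,
) -> float:
    """Total covariance cov_{g,u}(p_ig, p_jg) via the Law of Total Covariance.

    The first term is the cross-group covariance of posterior group means;
    the second averages the (negative) within-sample belief covariance over
    groups and is skipped when ``include_within_sample_cov`` is false (it is
    usually orders of magnitude smaller, which enables a fast path).
    """
    if i == j:
        raise ValueError("i == j: use total_variance")
    devi = moments.group_mean[i] - moments.grand_mean[i]
    devj = moments.group_mean[j] - moments.grand_mean[j]
    cov = float((devi * devj).mean())
    if include_within_sample_cov:
        n = len(moments.group_labels)
        at = post.alpha_totals
        per_sample = -post.alpha[i] * post.alpha[j] / (at**2 * (at + 1.0))
        within = 0.0
        for g in range(n):
            cols = moments.codes == g
            within += per_sample[cols].sum() / moments.group_sizes[g] ** 2
        cov += within / n
    return cov
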