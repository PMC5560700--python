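"""Permutation null distributions, tail probabilities and FDR estimates.

The null hypothesis is that two entities have no cross-group association.
Permuting raw counts would change sample depths (and hence every
posterior), and permuting per-sample estimates would change group means,
so instead each entity's vector of posterior *group means* is permuted
across groups.  Only the cross-group covariance term of the numerator
sees permuted values; the within-sample covariance term and both
denominator variances are permutation-invariant and are reused across
repetitions.

A single pooled null is kept (all pairs i < j, all K repetitions), as in
the classical Relevance Networks algorithm, giving the tail probability

    P(r >= t) = #{(i,j,k): i < j, r_ijk >= t} / (K m(m-1)/2)

and from it the expected false positives FP_t = P(r >= t) m(m-1)/2,
TP_t = max(N_t - FP_t, 0) and FDR_t = min(FP_t/N_t, 1) at any threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import BayesianCorrelation, CorrelationResult, GroupedPearsonCorrelation

__all__ = [
    "PermutationNull",
    "NetworkErrorEstimate",
    "build_null",
    "permuted_correlation_matrix",
    "permuted_bayesian_correlation",
    "tail_probability",
    "network_error_estimates",
    "threshold_at_fdr",
    "fdr_table",
]

# beyond this many pooled values, store a fixed-bin histogram instead
DENSE_LIMIT = 100_000_000
HIST_BINS = 10_000


@dataclass
class PermutationNull:
    """Pooled multiset of permuted correlations r_ijk.

    Stored either as a sorted array (``values``) or, for very large pools,
    as a fixed-bin histogram on [-1, 1] with quantization error <= 1e-4 in
    tail probability.
    """

    K: int
    method: str
    seed: int | None
    include_within_sample_cov: bool = False
    values: np.ndarray | None = None
    hist_counts: np.ndarray | None = None
    hist_edges: np.ndarray | None = None
    n_pairs_defined: int = 0  # defined pairs per repetition
    n_pairs_masked: int = 0

    @property
    def n_pooled(self) -> int:
        if self.values is not None:
            return len(self.values)
        return int(self.hist_counts.sum())

    def tail_probability(self, t) -> np.ndarray | float:
        """P(r >= t) under the pooled null; nonincreasing in t."""
        t = np.asarray(t, dtype=float)
        if self.values is not None:
            n = len(self.values)
            ge = n - np.searchsorted(self.values, t, side="left")
            out = ge / n if n else np.full(t.shape, np.nan)
        else:
            n = self.hist_counts.sum()
            cum = np.concatenate([[0], np.cumsum(self.hist_counts)])
            idx = np.searchsorted(self.hist_edges[1:], t, side="left")
            out = (n - cum[np.minimum(idx, len(self.hist_counts))]) / n
        return float(out) if out.ndim == 0 else out

    def save(self, path) -> None:
        """Archive as NPZ plus a JSON sidecar with the run metadata."""
        path = str(path)
        arrays = {}
        if self.values is not None:
            arrays["values"] = self.values
        else:
            arrays["hist_counts"] = self.hist_counts
            arrays["hist_edges"] = self.hist_edges
        np.savez_compressed(path, **arrays)
        meta = {
            "K": self.K,
            "method": self.method,
            "seed": self.seed,
            "include_within_sample_cov": self.include_within_sample_cov,
            "n_pairs_defined": self.n_pairs_defined,
            "n_pairs_masked": self.n_pairs_masked,
        }
        sidecar = path if path.endswith(".json") else path + ".json"
        with open(sidecar.replace(".npz.json", ".json"), "w") as fh:
            json.dump(meta, fh, indent=1)


@dataclass
class NetworkErrorEstimate:
    """Expected error rates of a relevance network at threshold t."""

    threshold: float
    n_links: int
    fp_expected: float
    tp_expected: float
    fdr: float  # NaN when n_links == 0 (undefined)

    @classmethod
    def from_counts(cls, threshold: float, n_links: int, fp_expected: float):
        """Assemble the estimate from an observed link count and an expected
        false-positive count: TP = max(N - FP, 0), FDR = min(FP/N, 1)."""
        tp = max(n_links - fp_expected, 0.0)
        fdr = min(fp_expected / n_links, 1.0) if n_links > 0 else float("nan")
        return cls(threshold, n_links, fp_expected, tp, fdr)

    @property
    def fdr_defined(self) -> bool:
        return self.n_links > 0


def _null_components(model):
    """Centered group means, denominators, mask and optional within term."""
    if isinstance(model, BayesianCorrelation):
        moments = model.moments_
        Mc = moments.group_mean - moments.grand_mean[:, None]
        tot = model.total_variance_
        W = model.within_sample_cov_term() if model.include_within_sample_cov else None
        method = "bayesian"
        include = model.include_within_sample_cov
    elif isinstance(model, GroupedPearsonCorrelation):
        M = model.group_means_
        Mc = M - M.mean(axis=1)[:, None]
        tot = model.total_variance_
        W = None
        method = "pearson"
        include = False
    else:
        raise TypeError("model must be a fitted correlation estimator")
    undefined = model.undefined_entities_
    return Mc, tot, W, undefined, method, include


def permuted_correlation_matrix(model, permutations: np.ndarray) -> np.ndarray:
    """Full permuted correlation matrix for one repetition.

    ``permutations`` is an (m, n_groups) integer array holding each
    entity's group permutation.  The arithmetic route is identical to the
    observed-matrix computation, so injecting the identity permutation for
    every entity reproduces the observed correlations exactly (bit for
    bit) off the diagonal.
    """
    Mc, tot, W, undefined, _, _ = _null_components(model)
    n = Mc.shape[1]
    Mp = np.take_along_axis(Mc, np.asarray(permutations, dtype=int), axis=1)
    num = Mp @ Mp.T / n
    if W is not None:
        num = num + W
    safe = np.where(undefined, 1.0, tot)
    r = num / np.sqrt(np.outer(safe, safe))
    r[undefined, :] = np.nan
    r[:, undefined] = np.nan
    return r


def build_null(model, K: int = 100, random_state=None) -> PermutationNull:
    """Pooled permutation null for a fitted correlation estimator.

    Each repetition draws an independent uniform permutation of every
    entity's group-mean vector; every pooled pair therefore compares two
    independently permuted profiles, distributionally equivalent to the
    pairwise "unpermuted i versus permuted j" scheme while requiring only
    O(K m) permutations.  Reproducible given (random_state, K).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Mc, tot, W, undefined, method, include = _null_components(model)
    m, n = Mc.shape
    rng = np.random.default_rng(random_state)
    safe = np.where(undefined, 1.0, tot)
    denom = np.sqrt(np.outer(safe, safe))
    iu, ju = np.triu_indices(m, k=1)
    keep = ~(undefined[iu] | undefined[ju])
    iu, ju = iu[keep], ju[keep]
    n_defined = len(iu)
    n_masked = m * (m - 1) // 2 - n_defined

    pooled_size = K * n_defined
    use_hist = pooled_size > DENSE_LIMIT
    if use_hist:
        edges = np.linspace(-1.0 - 1e-9, 1.0 + 1e-9, HIST_BINS + 1)
        counts = np.zeros(HIST_BINS, dtype=np.int64)
    else:
        chunks = []
    for _ in range(K):
        perms = np.argsort(rng.random((m, n)), axis=1)
        Mp = np.take_along_axis(Mc, perms, axis=1)
        num = Mp @ Mp.T / n
        if W is not None:
            num = num + W
        vals = (num / denom)[iu, ju]
        if use_hist:
            counts += np.histogram(np.clip(vals, -1.0, 1.0), bins=edges)[0]
        else:
            chunks.append(vals)
    seed = random_state if isinstance(random_state, (int, np.integer)) else None
    if use_hist:
        return PermutationNull(
            K, method, seed, include, None, counts, edges, n_defined, n_masked
        )
    values = np.sort(np.concatenate(chunks))
    return PermutationNull(K, method, seed, include, values, None, None, n_defined, n_masked)


def permuted_bayesian_correlation(
    model: BayesianCorrelation, i: int, j: int, rho
) -> float:
    """Permuted Bayesian correlation for one pair and one explicit group
    permutation ``rho`` (a bijection on group indices).

    Only entity j's group means are reordered, and only in the cross-group
    covariance term; the within-sample covariance term (when the model
    includes it) and both denominator variances stay unpermuted.  The
    identity permutation recovers the observed correlation (bit-exact
    reproduction is guaranteed by :func:`permuted_correlation_matrix`,
    which shares the observed matrix's arithmetic route).
    """
    rho = np.asarray(rho, dtype=int)
    n = len(model.group_labels_)
    if sorted(rho.tolist()) != list(range(n)):
        raise ValueError("rho must be a bijection on group indices 0..n-1")
    moments = model.moments_
    devi = moments.group_mean[i] - moments.grand_mean[i]
    devj = (moments.group_mean[j] - moments.grand_mean[j])[rho]
    num = float((devi * devj).mean())
    if model.include_within_sample_cov:
        num += float(model.within_sample_cov_term()[i, j])
    ti, tj = model.total_variance_[i], model.total_variance_[j]
    if ti <= 0 or tj <= 0:
        return float("nan")
    return num / np.sqrt(ti * tj)


def tail_probability(null: PermutationNull, t: float) -> float:
    """Fraction of pooled permuted correlations >= t (inclusive)."""
    return null.tail_probability(t)


def _count_links(observed: CorrelationResult, t: float) -> int:
    vals = observed.defined_upper_values()
    return int((vals >= t).sum())


def network_error_estimates(
    null: PermutationNull, observed: CorrelationResult, t: float
) -> NetworkErrorEstimate:
    """FP/TP/FDR estimates for the network thresholded at t."""
    if null.method != observed.method:
        raise ValueError(
            f"null built for {null.method!r} but observed is {observed.method!r}"
        )
    if null.n_pairs_defined != observed.n_defined_pairs():
        raise ValueError("null and observed cover different entity-pair sets")
    n_links = _count_links(observed, t)
    fp = null.tail_probability(t) * observed.n_defined_pairs()
    return NetworkErrorEstimate.from_counts(t, n_links, fp)


def threshold_at_fdr(
    null: PermutationNull, observed: CorrelationResult, max_fdr: float
) -> NetworkErrorEstimate | None:
    """Most permissive observed threshold whose estimated FDR is <= max_fdr.

    Candidate thresholds are the observed correlations themselves; the one
    admitting the most links while keeping FDR_t <= max_fdr is returned
    (None when even the strictest threshold fails).
    """
    vals = np.sort(observed.defined_upper_values())[::-1]
    if len(vals) == 0:
        return None
    n_pairs = len(vals)
    tails = null.tail_probability(vals)
    n_links = np.arange(1, n_pairs + 1)
    fdr = np.minimum(tails * n_pairs / n_links, 1.0)
    ok = np.flatnonzero(fdr <= max_fdr)
    if len(ok) == 0:
        return None
    best = ok[-1]  # most links
    return NetworkErrorEstimate.from_counts(
        float(vals[best]), int(n_links[best]), float(tails[best] * n_pairs)
    )


def fdr_table(
    null: PermutationNull, observed: CorrelationResult, thresholds
) -> pd.DataFrame:
    """(t, N_t, FP_t, TP_t, FDR_t) over a threshold grid."""
    rows = []
    for t in thresholds:
        est = network_error_estimates(null, observed, float(t))
        rows.append(
            {
                "t": est.threshold,
                "N_t": est.n_links,
                "FP_t": est.fp_expected,
                "TP_t": est.tp_expected,
                "FDR_t": est.fdr,
            }
        )
    return pd.DataFrame(rows)
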