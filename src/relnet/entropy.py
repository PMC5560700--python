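"""Entropy filtering of expression profiles.

Correlations that hinge on one or two outlier samples show up as
low-entropy expression profiles: nearly all samples fall in one histogram
bin.  For each entity the maximum-likelihood expression values across all
samples are binned into 10 equal-width bins spanning [min, max], and the
Shannon entropy (bits) of the bin fractions is computed; entities in the
lowest percentile of entropy can be discarded before network construction.
This mirrors the filtering step of the classical Relevance Networks
algorithm and is computed on maximum-likelihood fractions, not posterior
means, so Bayesian and classical runs filter identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix

__all__ = ["EntropyProfile", "EntropyFilter", "expression_entropy", "filter_low_entropy"]

N_BINS = 10


@dataclass
class EntropyProfile:
    """Per-entity expression entropy over 10 equal-width bins."""

    entropy: np.ndarray  # bits, in [0, log2(10)]
    bin_fractions: np.ndarray  # (m, 10); all-zero row when low == high
    low: np.ndarray  # A = min over samples
    high: np.ndarray  # B = max over samples
    entity_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.entity_ids is None:
            self.entity_ids = np.array(
                [f"e{i}" for i in range(len(self.entropy))], dtype=object
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"A": self.low, "B": self.high, "H": self.entropy},
            index=pd.Index(self.entity_ids, name="entity_id"),
        )


def _entropy_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    m, s = values.shape
    low = values.min(axis=1)
    high = values.max(axis=1)
    fractions = np.zeros((m, N_BINS))
    entropy = np.zeros(m)
    span = high - low
    # ranges within a few ulps of zero (e.g. identical fractions computed
    # at different depths) are degenerate: H = 0, no binning
    tiny = 16 * np.finfo(float).eps * np.maximum(np.abs(low), np.abs(high))
    nondegenerate = span > tiny
    for i in np.flatnonzero(nondegenerate):
        # half-open bins [A + k w, A + (k+1) w), last bin closed at B
        idx = np.floor((values[i] - low[i]) / span[i] * N_BINS).astype(int)
        idx = np.clip(idx, 0, N_BINS - 1)
        counts = np.bincount(idx, minlength=N_BINS)
        f = counts / s
        fractions[i] = f
        nz = f > 0
        entropy[i] = -(f[nz] * np.log2(f[nz])).sum()
    # degenerate rows (A == B): H = 0, fractions all-zero by definition
    return entropy, fractions, low, high


def expression_entropy(expr: ExpressionMatrix | np.ndarray) -> EntropyProfile:
    """Shannon entropy (bits) of each entity's expression histogram.

    Invariant to multiplying an entity's values by a positive constant,
    so fraction and RPM units give identical entropies.
    """
    if isinstance(expr, ExpressionMatrix):
        values, ids = expr.values, expr.entity_ids
    else:
        values, ids = np.asarray(expr, dtype=float), None
    entropy, fractions, low, high = _entropy_rows(values)
    return EntropyProfile(entropy, fractions, low, high, ids)


def _discard_order(profile: EntropyProfile) -> np.ndarray:
    """Entity indices sorted by (entropy, entity id): the deterministic
    discard order used for percentile tie-breaking."""
    ids = np.asarray(profile.entity_ids, dtype=str)
    return np.lexsort((ids, profile.entropy))


def filter_low_entropy(profile: EntropyProfile, h_thresh_percent: float = 10.0):
    """Kept entity ids after discarding the lowest ``h_thresh_percent`` of
    entropies.

    Exactly ``floor(m * h_thresh_percent / 100)`` entities are discarded:
    all entities strictly below the percentile value, with ties at the
    boundary resolved by entity id order.
    """
    if not 0.0 <= h_thresh_percent <= 100.0:
        raise ValueError("h_thresh_percent must be in [0, 100]")
    m = len(profile.entropy)
    k = int(np.floor(m * h_thresh_percent / 100.0))
    order = _discard_order(profile)
    keep_mask = np.ones(m, dtype=bool)
    keep_mask[order[:k]] = False
    return [profile.entity_ids[i] for i in np.flatnonzero(keep_mask)]


class EntropyFilter(BaseEstimator, TransformerMixin):
    """Transformer discarding the lowest-entropy entities (features).

    ``X`` is (n_samples, n_entities); counts are converted to per-sample
    maximum-likelihood fractions before binning when ``normalize_counts``.
    """

    def __init__(self, h_thresh_percent: float = 10.0, normalize_counts: bool = True):
        self.h_thresh_percent = h_thresh_percent
        self.normalize_counts = normalize_counts

    def fit(self, X, y=None, entity_ids=None):
        if not 0.0 <= self.h_thresh_percent <= 100.0:
            raise ValueError("h_thresh_percent must be in [0, 100]")
        X = np.asarray(X, dtype=float)
        values = X.T
        if self.normalize_counts:
            totals = values.sum(axis=0)
            values = values / np.where(totals == 0, 1.0, totals)
        entropy, fractions, low, high = _entropy_rows(values)
        self.n_features_in_ = values.shape[0]
        self.profile_ = EntropyProfile(entropy, fractions, low, high, entity_ids)
        self.entropy_ = entropy
        k = int(np.floor(self.n_features_in_ * self.h_thresh_percent / 100.0))
        support = np.ones(self.n_features_in_, dtype=bool)
        support[_discard_order(self.profile_)[:k]] = False
        self.support_ = support
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]
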