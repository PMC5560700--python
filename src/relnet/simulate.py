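"""Synthetic grouped count data with known ground truth.

The generator realizes the sampling model assumed by the correlation
machinery: each sample's counts are one multinomial draw at that sample's
sequencing depth from latent per-sample fractions.  The latent fractions
are built on a log scale — a log-normal baseline per entity spanning
several orders of magnitude, an independent per-group effect per entity,
a per-group factor shared by the members of each planted co-expression
module (inducing cross-group correlation within modules), and per-sample
log-normal noise — then renormalized to sum to one per sample.

Sequencing depth is heterogeneous and group-structured: each group has a
characteristic depth on a geometric ladder spanning the configured range
(about 150-fold by default, as real cohorts differ systematically in
depth per condition), with log-uniform jitter within the group.

Planted "spurious" pairs emulate correlation artifacts: two entities with
zero true expression that each receive 1-5 artifact reads (contamination
or mismapping, not part of the multinomial draw) in the single deepest
sample.  Classical Pearson correlation on group means sees two perfectly
aligned single-spike profiles; the Bayesian correlation knows how little
evidence a couple of reads carry and suppresses the pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .correlation import CorrelationResult
from .io import CountMatrix, ExpressionMatrix, GroupAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "split_half",
    "mad_between",
    "expression_bins",
    "pove",
]


@dataclass
class SimulationConfig:
    """Generator parameters; the defaults define the standard test-bed.

    Log-scale standard deviations are in natural-log units.
    """

    m: int = 200
    n_groups: int = 10
    samples_per_group: int = 6
    depth_range: tuple = (10_000, 1_500_000)
    module_sizes: tuple = (8, 8)
    n_spurious_pairs: int = 2
    sigma_baseline: float = 1.0  # spread of baseline abundances across entities
    sigma_group: float = 0.7  # independent per-entity group effect
    sigma_module: float = 1.0  # shared per-module group contrast (standardized)
    sigma_module_member: float = 0.05  # residual group effect of members
    sigma_within: float = 0.15  # per-sample noise
    module_baseline_scale: float = 0.3
    module_baseline_sigma: float = 0.3
    spurious_read_range: tuple = (1, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must be positive and ordered")
        n_special = sum(self.module_sizes) + 2 * self.n_spurious_pairs
        if n_special > self.m:
            raise ValueError(
                f"modules and spurious pairs need {n_special} entities but m={self.m}"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("depth_range", "module_sizes", "spurious_read_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Latent state of a simulation: known only because we generated it."""

    true_fractions: np.ndarray  # (m, n_samples), columns sum to 1
    module_of: dict  # entity id -> module index (absent = background)
    planted_correlated_pairs: set  # frozensets of entity ids
    planted_spurious_pairs: set
    spurious_samples: dict  # pair (frozenset) -> sample id of the artifact
    module_members: list = field(default_factory=list)


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Named substream: entity/module/sample draws are independent of how
    many other entities exist."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


_ENTITY, _MODULE, _SAMPLE, _STRUCTURE = 1, 2, 3, 4


def simulate_counts(config: SimulationConfig):
    """Draw a grouped count dataset.

    Returns ``(CountMatrix, GroupAssignment, GroundTruth)``; bit-identical
    across runs for a fixed config.
    """
    m, n, ng = config.m, config.n_groups, config.samples_per_group
    S = n * ng
    g_of = np.repeat(np.arange(n), ng)
    entity_ids = np.array([f"ent{i:04d}" for i in range(m)], dtype=object)
    sample_ids = np.array([f"sample{s:03d}" for s in range(S)], dtype=object)
    group_labels = np.array([f"G{g:02d}" for g in range(n)], dtype=object)

    struct = _stream(config.seed, _STRUCTURE)
    special = struct.choice(m, size=sum(config.module_sizes) + 2 * config.n_spurious_pairs,
                            replace=False)
    module_members, offset = [], 0
    for size in config.module_sizes:
        module_members.append(np.sort(special[offset:offset + size]))
        offset += size
    spurious_entities = special[offset:]
    spurious_pairs = [
        (spurious_entities[2 * k], spurious_entities[2 * k + 1])
        for k in range(config.n_spurious_pairs)
    ]

    # group-structured sequencing depths on a geometric ladder
    lo, hi = config.depth_range
    jitter = 0.4
    group_depth = np.geomspace(lo * np.e**jitter, hi * np.e**-jitter, n)
    depths = np.empty(S)
    for s in range(S):
        depths[s] = group_depth[g_of[s]] * np.exp(
            _stream(config.seed, _SAMPLE, s).uniform(-jitter, jitter)
        )
    depths = np.maximum(depths.astype(int), 1)

    # each module's cross-group contrast is standardized to unit spread so
    # every planted module represents the same effect size
    module_factors = []
    for k in range(len(config.module_sizes)):
        f = _stream(config.seed, _MODULE, k).normal(0.0, 1.0, size=n)
        module_factors.append((f - f.mean()) / f.std())

    member_of = {}
    for k, members in enumerate(module_members):
        for i in members:
            member_of[int(i)] = k

    weights = np.zeros((m, S))
    for i in range(m):
        rng_i = _stream(config.seed, _ENTITY, i)
        z_base = rng_i.normal()
        z_group = rng_i.normal(0.0, 1.0, size=n)
        z_within = rng_i.normal(0.0, 1.0, size=S)
        if i in member_of:
            base = config.module_baseline_scale * np.exp(
                config.module_baseline_sigma * z_base
            )
            group_effect = np.exp(
                config.sigma_module * module_factors[member_of[i]]
                + config.sigma_module_member * z_group
            )
        else:
            base = np.exp(config.sigma_baseline * z_base)
            group_effect = np.exp(config.sigma_group * z_group)
        weights[i] = base * group_effect[g_of] * np.exp(config.sigma_within * z_within)
    for i, j in spurious_pairs:
        weights[i] = 0.0
        weights[j] = 0.0

    fractions = weights / weights.sum(axis=0)
    counts = np.empty((m, S))
    for s in range(S):
        counts[:, s] = _stream(config.seed, _SAMPLE, s, 1).multinomial(
            int(depths[s]), fractions[:, s]
        )

    # artifact reads for spurious pairs: k-th deepest sample for pair k
    deepest = np.argsort(-depths, kind="stable")
    spurious_samples = {}
    rlo, rhi = config.spurious_read_range
    for k, (i, j) in enumerate(spurious_pairs):
        s_star = int(deepest[k])
        reads = struct.integers(rlo, rhi + 1, size=2)
        counts[i, s_star] = reads[0]
        counts[j, s_star] = reads[1]
        spurious_samples[frozenset((entity_ids[i], entity_ids[j]))] = sample_ids[s_star]

    cm = CountMatrix(counts, entity_ids, sample_ids)
    groups = GroupAssignment.from_labels(sample_ids, group_labels[g_of])
    planted = {
        frozenset((entity_ids[a], entity_ids[b]))
        for members in module_members
        for ai, a in enumerate(members)
        for b in members[ai + 1:]
    }
    truth = GroundTruth(
        true_fractions=fractions,
        module_of={entity_ids[i]: k for i, k in member_of.items()},
        planted_correlated_pairs=planted,
        planted_spurious_pairs={
            frozenset((entity_ids[i], entity_ids[j])) for i, j in spurious_pairs
        },
        spurious_samples=spurious_samples,
        module_members=[[entity_ids[i] for i in members] for members in module_members],
    )
    return cm, groups, truth


def split_half(groups: GroupAssignment, seed: int):
    """Random split of samples into two folds, balanced within each group.

    Each group's samples are divided as evenly as possible (difference at
    most 1, side of the odd sample randomized); single-sample groups go
    wholly to one fold and are flagged.
    """
    rng = np.random.default_rng(seed)
    fold1, fold2 = [], []
    for label in groups.labels:
        members = sorted(groups.members(label))
        if len(members) == 1:
            logger.warning("group %r has a single sample; fold split is degenerate", label)
        perm = [members[i] for i in rng.permutation(len(members))]
        k = len(perm) // 2
        if len(perm) % 2 == 1 and rng.random() < 0.5:
            k += 1
        fold1.extend(perm[:k])
        fold2.extend(perm[k:])
    return sorted(fold1), sorted(fold2)


def mad_between(
    corrA: CorrelationResult,
    corrB: CorrelationResult,
    binsX=None,
    binsY=None,
) -> float:
    """Mean absolute deviation between two correlation sets.

    With ``binsX``/``binsY`` given (entity id collections), averages
    |r_A(x, y) - r_B(x, y)| over cross-bin pairs x in X, y in Y (x != y);
    otherwise over all pairs.  Pairs masked in either result are excluded
    from numerator and denominator.
    """
    ids = list(corrA.entity_ids)
    if list(corrB.entity_ids) != ids:
        raise ValueError("correlation results cover different entities")
    index = {e: k for k, e in enumerate(ids)}
    xi = np.array([index[e] for e in (binsX if binsX is not None else ids)])
    yi = np.array([index[e] for e in (binsY if binsY is not None else ids)])
    diff = np.abs(corrA.r[np.ix_(xi, yi)] - corrB.r[np.ix_(xi, yi)])
    mask = corrA.pair_mask | corrB.pair_mask
    bad = mask[np.ix_(xi, yi)] | (xi[:, None] == yi[None, :])
    n_excluded = int(bad.sum() - (xi[:, None] == yi[None, :]).sum())
    if n_excluded:
        logger.info("mad_between: excluded %d masked pairs", n_excluded)
    good = ~bad
    if not good.any():
        return float("nan")
    return float(diff[good].mean())


def expression_bins(expr: ExpressionMatrix, n_bins: int = 21) -> np.ndarray:
    """Entity bin index (0 = lowest expression) by mean RPM across samples.

    Entities are ranked by mean expression (ties broken by entity id) and
    split into ``n_bins`` groups whose sizes differ by at most one.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    mean_expr = expr.values.mean(axis=1)
    ids = np.asarray(expr.entity_ids, dtype=str)
    order = np.lexsort((ids, mean_expr))
    bins = np.empty(len(order), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def pove(expr: ExpressionMatrix, groups: GroupAssignment) -> np.ndarray:
    """Percentage of each entity's expression variance across samples that
    is explained by between-group differences (one-way decomposition)."""
    codes = groups.codes(expr.sample_ids)
    n = codes.max() + 1
    if n < 2:
        raise ValueError("at least 2 groups required")
    values = expr.values
    grand = values.mean(axis=1)
    total = ((values - grand[:, None]) ** 2).mean(axis=1)
    between = np.zeros_like(total)
    for g in range(n):
        cols = codes == g
        ngs = cols.sum()
        between += ngs * (values[:, cols].mean(axis=1) - grand) ** 2
    between /= values.shape[1]
    out = np.zeros_like(total)
    ok = total > 0
    out[ok] = 100.0 * between[ok] / total[ok]
    return out
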