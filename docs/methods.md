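# Methods

## Model and estimator

Counts for sample *s* of group *g* are modeled as one multinomial draw of
depth R_gs over the m entities with latent fractions p_igs. Correlations
are defined on the fraction scale; fractions are proportional to RPM, and
correlations are scale-invariant, so the choice of unit is immaterial for
the Bayesian estimator (the Pearson baseline is computed on RPM, the unit
practitioners use).

Beliefs about each sample's fractions are Dirichlet. The symmetric prior
weight is 1/m per entity, i.e. a single pseudo-read spread over the whole
entity universe per sample; this keeps posterior means for zero-count
entities at (1/m)/α_gs ≈ 1/(m·R_gs), shrinking with depth, and has low
bias for entities represented by few reads. A per-entity prior vector is
accepted for users with informative priors, but the scalar 1/m is the
default and the tested configuration.

All moments used are closed-form:

- per sample: E_u(p_igs) = α_igs/α_gs,
  var_u = α_igs(α_gs−α_igs)/(α_gs²(α_gs+1)),
  cov_u = −α_igs α_jgs/(α_gs²(α_gs+1)) (negative: fractions sum to one);
- per group (beliefs independent across samples): the mean of sample
  means, and sample variances/covariances summed and divided by n_g²;
- total, via the Laws of Total Variance/Covariance with groups weighted
  equally (population-style 1/n and 1/n_g factors, not n−1 denominators —
  correlations are invariant to a common factor, but the reported
  variance components follow this convention).

The Bayesian correlation divides the total covariance by the geometric
mean of total variances. The diagonal is reported as 1 by convention —
the ratio applied to i = i does not equal 1 at finite depth — and
self-pairs never participate in edge or null counting. Entities with
zero total variance are masked (NaN), never silently zeroed; with a
positive prior this arises only in pathological cases, but the contract
is explicit.

### Fast path

The within-sample covariance term E_g(cov_u) involves products of two
small fractions and is usually orders of magnitude below the cross-group
term, so `include_within_sample_cov=False` (the default) skips it in both
the observed correlations and the null. On the default synthetic test-bed
the largest resulting change in any correlation is ~1e-5 (asserted at
1e-3 in the tests). The exact term remains available and is used by the
acceptance checks.

## Permutation null and error estimates

Permuting raw counts would alter sample depths and therefore every
posterior; permuting per-sample estimates would alter group means. The
null therefore permutes each entity's vector of posterior group means
across groups, only in the cross-group covariance term; the within-sample
term and both denominator variances are permutation-invariant and are
computed once. Each of the K repetitions (default 100) draws an
independent uniform permutation per entity, so each pooled pair compares
two independently permuted profiles — distributionally equivalent to
"unpermuted i versus permuted j" at O(K·m) permutations instead of
O(K·m²). Pooled values from all pairs i < j and all repetitions form a
single null (per-pair nulls would be sounder but far more expensive; the
pooled choice matches the classical algorithm this method updates).
Masked pairs are excluded from both numerator and denominator of the
tail probability; the effective pair count is recorded.

Thresholding uses the inclusive rule r ≥ t everywhere. At threshold t:
FP_t = P(r ≥ t)·(defined pairs), TP_t = max(N_t − FP_t, 0),
FDR_t = min(FP_t/N_t, 1), undefined when N_t = 0. `threshold_at_fdr`
returns the most permissive observed correlation value whose estimated
FDR meets the target, which maximizes the number of reported links.
Pooled values are stored as a sorted array up to 1e8 values; beyond that
a 10,000-bin histogram on [−1, 1] is used, with tail-probability
quantization error ≤ 1e-4.

Identity-permutation consistency is an exact (bitwise) contract of
`permuted_correlation_matrix`, which shares the observed matrix's
arithmetic route; the scalar per-pair formula agrees to ~1e-15 relative
(floating-point summation order).

## Entropy filter

Computed on maximum-likelihood fractions R_igs/R_gs (not posterior
means), so Bayesian and classical runs filter identically. Ten
equal-width bins span [A, B] = [min, max] over all samples; bins are
half-open with the last closed at B so the maximum is counted; H = 0
when A = B. Ranges within a few ulps of zero are treated as degenerate —
identical fractions computed at different depths can differ by one ulp
and must not be binned as structure. Filtering discards exactly
⌊m·H_thresh/100⌋ entities: all entities strictly below the percentile
value, ties at the boundary resolved by entity id, so the filter is
deterministic and monotone in the threshold. The default H_thresh is 10%
(the classical algorithm's original suggestion was 5%).

## Genomic locality

Edge categories are assigned in strict priority order: stem-loop (the two
mature miRNAs share a precursor anywhere in the genome), transcript
(contained in the same transcribed entity but not the same precursor),
near (any pair of genomic occurrences on the same chromosome with
closest-endpoint gap ≤ 10 kb, 0 when overlapping, strand-agnostic,
1-based inclusive coordinates), cluster (same connected component of the
near relation over all occurrences of all mature miRNAs, but not directly
near), else non-local. A mature miRNA may occur at several loci; an edge
qualifies for a category if any occurrence pair qualifies. Entities with
no genomic record are non-local with a warning. Whether "near" should be
measured between starts, midpoints or closest endpoints is a genuine
convention choice; closest endpoints is this package's contract.

## Synthetic test-bed

The generator draws exactly the sampling model above: per sample, one
multinomial draw at that sample's depth from latent fractions built on a
log scale — log-normal baseline per entity (σ = 1.0 in natural log,
roughly three decades of abundance across 200 entities), an independent
per-group effect per entity (σ = 0.7), a shared per-group contrast for
each planted module, and per-sample noise (σ = 0.15) — renormalized per
sample.

Design choices that matter and why:

- **Group-structured depths.** Each group sits on a geometric depth
  ladder spanning the configured range (default 1e4–1.5e6, about
  150-fold) with log-uniform jitter within groups. Real cohorts differ
  systematically in depth per condition, and this structure is
  load-bearing: a zero-count entity's posterior mean is α⁰/α_gs, so
  depth structure both spreads prior-driven group means and concentrates
  posterior uncertainty in shallow groups. Without it, low-count
  coincidences cannot be distinguished from signal by any estimator at
  this scale.
- **Standardized module contrasts.** Each module's per-group factor
  vector is z-scored across groups before scaling by σ_module = 1.0, so
  every planted module represents the same effect size; with only 10
  groups, raw draws occasionally produce a near-flat module that no
  method could detect, which would make ground truth meaningless rather
  than the test harder. Members add a small residual group effect
  (σ = 0.05). With 10 groups, a detection threshold near r ≈ 0.94 is
  forced by chance alignments alone (Fisher-z spread at n = 10), so
  planted pairs are designed to sit near r ≈ 0.99.
- **Moderate compositional footprint.** Module members' baselines are
  scaled (0.3× a typical background entity) so that module up-swings
  never dominate a sample's composition; a dominant block would impose a
  common-mode signal on all other entities through renormalization and
  blur the distinction between planted and background pairs.
- **Planted artifact pairs.** Two entities with zero true expression
  each receive 1–5 reads in the single deepest sample, overwriting the
  (zero) multinomial draw, and sample totals are recomputed; these model
  contamination or mismapping, which is why they are not part of the
  multinomial draw and why they appear where depth is greatest — an
  artifact at a few reads is only observed in deep libraries. The
  classical estimator sees two perfectly aligned single-spike profiles
  (r ≈ 1); the Bayesian estimator's uncertainty terms, dominated by the
  prior's pseudocount spread across the depth ladder, suppress the pair
  to r ≈ 0.02–0.05.
- **Named random streams.** All randomness flows from one seed through
  keyed substreams (per entity, per module, per sample), so enlarging
  the entity universe does not perturb existing entities' draws.

What the generator does not emulate: overdispersion beyond multinomial
sampling, correlated biological noise across groups, batch effects,
ambiguous multi-mapping, and the extreme tail of real abundance
distributions (five-plus decades). Passing tests therefore demonstrate
correctness of the estimators under the stated sampling model and the
qualitative phenomena that motivate the method, not performance claims
on any real cohort.

## Problem sizes and numerics

The default test-bed is m = 200 entities, 10 groups × 6 samples,
K = 100 permutations (≈2×10⁶ pooled null values), chosen so the full
pipeline runs in seconds on one core while leaving all the phenomena of
interest visible. Calibration checks use a signal-free m = 100
configuration. Monte-Carlo validation of the closed-form moments uses
10⁶ Dirichlet draws against 3-standard-error bands. Oracle comparisons
against naive-loop implementations are at 1e-10 relative tolerance;
belief-conservation identities at 1e-9 absolute. Results are invariant
to entity order and to sample order within groups at the 1e-12 level
(asserted in tests).

## Known limitations

- The pooled null understates per-pair tail variation; clustered chance
  alignments (several entities spiking in the same group) make the
  realized false-discovery count overdispersed relative to the estimate,
  which is why the test-bed asserts realized FDR ≤ 2× the estimate
  rather than equality.
- With few groups (n ≈ 10), thresholds near 0.94 are unavoidable at
  FDR ≤ 0.1; weaker but real co-expression is undetectable at this
  scale regardless of estimator.
- The entropy filter's bin-edge convention (half-open, last bin closed)
  is one of several defensible choices; entities exactly at interior
  edges can move bins under other conventions.
- `aggregate_isoform_quantification` sums printed counts as-is; how
  multi-mapped reads were weighted upstream is the data producer's
  choice and is not re-normalized here.
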