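# relnet — Bayesian Relevance Networks for sequencing count data

`relnet` builds co-expression networks from grouped high-throughput
sequencing counts (miRNA-seq, RNA-seq, single-cell counts) while
accounting for the measurement uncertainty that comes with finite
sequencing depth. Classical relevance networks threshold Pearson
correlations of normalized expression; with count data this is easily
fooled — two transcripts seen together in a single sample at two reads
each correlate at r ≈ 1 even though almost nothing was measured.

## The model

Reads in sample *s* of group *g* are multinomial over the *m* entities,

    (R_1gs, …, R_mgs) ~ Multinom(R_gs; p_1gs, …, p_mgs),

where *p_igs* is the latent expression fraction. With a symmetric
Dirichlet prior of weight 1/*m* per entity, the posterior for a sample is
Dirichlet(α_1gs, …, α_mgs) with α_igs = 1/m + R_igs, giving closed-form
posterior moments for each *p_igs* and, by belief independence across
samples, for the group means *p_ig*. The Bayesian correlation of entities
*i* and *j* applies the Laws of Total Variance and Covariance jointly over
group identity and posterior uncertainty:

    r_ij^B = [ cov_g(E_u p_ig, E_u p_jg) + E_g(cov_u(p_ig, p_jg)) ]
             / sqrt( var_{g,u}(p_ig) · var_{g,u}(p_jg) )

Uncertainty inflates the denominator, so poorly measured entities are
moderated toward zero, while deeply sequenced entities converge to the
classical grouped Pearson correlation. Significance comes from a pooled
permutation null: each entity's vector of posterior group means is
permuted across groups (the within-sample covariance term and the
denominators are permutation-invariant), and the pooled tail gives
P(r ≥ t), expected false positives FP_t = P(r ≥ t)·m(m−1)/2, and
FDR_t = min(FP_t/N_t, 1) at any threshold *t*.

The package also provides the classical baseline (grouped Pearson on
RPM), the 10-bin entropy filter for outlier-driven profiles, network
construction/difference/export (SIF, GraphML, TSV), genomic locality
annotation of edges from miRBase GFF3 and ENSEMbl GTF (stem-loop /
transcript / near / cluster / non-local), and a synthetic-data generator
with planted co-expression modules and planted low-count artifact pairs.

## Worked example

```python
import numpy as np
from relnet import (SimulationConfig, simulate_counts,
                    BayesianRelevanceNetwork, pearson_group_correlation_matrix)

cm, groups, truth = simulate_counts(SimulationConfig(seed=1))
labels = [groups.labels[c] for c in groups.codes(cm.sample_ids)]

net = BayesianRelevanceNetwork(target_fdr=0.1, K=100, random_state=1,
                               include_within_sample_cov=True)
net.fit(cm.counts.T, labels, entity_ids=cm.entity_ids)
print(f"threshold {net.threshold_:.4f}: {net.network_.n_links} links, "
      f"estimated FDR {net.error_estimate_.fdr:.3f}")

planted = truth.planted_correlated_pairs
hits = sum(1 for p in planted if p in net.network_.edge_set())
print(f"recovered {hits}/{len(planted)} planted module pairs")

rp = pearson_group_correlation_matrix(cm, groups)
idx = {e: i for i, e in enumerate(cm.entity_ids)}
pair = min(tuple(sorted(p)) for p in truth.planted_spurious_pairs)
i, j = (idx[e] for e in pair)
print(f"artifact pair: Pearson {rp.r[i, j]:.4f}, Bayesian {net.result_.r[i, j]:.4f}")
```

Output:

```
threshold 0.9460: 57 links, estimated FDR 0.088
recovered 55/56 planted module pairs
artifact pair: Pearson 1.0000, Bayesian 0.0199
```

The network at the permutation-chosen threshold recovers essentially all
planted co-expressed pairs at the advertised error rate, while the pair
of entities sharing only a couple of artifact reads in one deep sample —
a perfect correlation for the classical estimator — is moderated to
r^B ≈ 0.02.

The same pipeline is scriptable from the shell:

```sh
relnet simulate --seed 1 --out-dir sim/
relnet correlate --counts sim/counts.tsv --groups sim/groups.tsv --method both --out-dir corr/
relnet null --counts sim/counts.tsv --groups sim/groups.tsv -K 100 --seed 1 --out-dir null/
relnet network --correlation corr/correlation_bayesian.tsv --t 0.94 --format sif --out-dir net/
```

## Layout

- `relnet.io` — count-matrix / group-table I/O (TSV, Matrix Market),
  TCGA-style isoform-quantification aggregation to mature miRNAs,
  depth normalization (fraction, RPM)
- `relnet.posterior` — Dirichlet posterior and closed-form moments
- `relnet.correlation` — `BayesianCorrelation`, `GroupedPearsonCorrelation`
- `relnet.entropy` — expression-entropy profile and `EntropyFilter`
- `relnet.permutation` — pooled permutation null, tail probabilities,
  FP/TP/FDR estimates, FDR-targeted thresholding
- `relnet.network` — thresholding, link-count matching, difference
  networks, genomic-locality annotation, export
- `relnet.simulate` — synthetic generator with ground truth, split-half
  folds, MAD, expression bins, POVE
- `relnet.pipeline` — `BayesianRelevanceNetwork`, the end-to-end estimator
- `relnet.cli` — `relnet` command-line tool
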