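# lectnet

Differential co-expression network analysis for small gene panels, with
degree-based hub detection, cross-cohort validation, and survival
stratification of subjects by hub-gene expression.

## The problem

Genes can change how they act in disease without changing how much they are
expressed: a receptor may acquire new co-regulation partners in a tumor while
its mean transcript level stays flat. Classical differential expression misses
this. Differential *co-expression* analysis asks, for every pair of genes in a
panel, whether their correlation across samples is significantly stronger in
tumors than in healthy tissue, builds a network from the pairs that are, and
nominates the most connected genes ("hubs") as candidate disease players. The
motivating application is a panel of lectin genes (siglecs, galectins, C-type
lectins) in glioblastoma versus healthy brain cortex, where hub lectins were
then tested as survival markers — but the machinery is generic to any
two-condition panel study.

## The method

For each gene pair with Spearman correlations ρ_T (tumor, n_T samples) and
ρ_C (control, n_C samples), the correlations are Fisher Z-transformed
(z = arctanh ρ) and compared with

```
Z = (z_T − z_C) / sqrt( 1/(n_T − 3) + 1/(n_C − 3) )
```

which is approximately standard normal when the true correlations are equal.
The pipeline:

1. **Preprocess** — subset counts to the panel, drop genes with total counts
   < 500 across samples, normalize with median-of-ratios size factors,
   log2(x + 1) transform.
2. **Differential network** — Spearman matrices per condition (positive tumor
   links only), edges where Z ≥ 3.
3. **Hubs** — nodes in the top 20% of the degree distribution over connected
   nodes (80th-percentile rule).
4. **Validation** — a second tumor cohort is thresholded so its differential
   network matches the discovery network's density; hub sets and degree
   rankings (Spearman) are compared.
5. **Annotation** — per-gene Welch t-test with Benjamini–Hochberg FDR;
   a gene is differentially expressed iff |log2FC| ≥ 1.5 and adj-p < 0.05.
6. **Survival** — subjects clustered into low/high expressors of two marker
   genes by fuzzy C-means (or split at per-marker medians), then compared by
   Kaplan–Meier curves, the log-rank test, and a Mantel–Haenszel hazard
   ratio (O₁/E₁)/(O₂/E₂).

A synthetic-data module simulates the whole design — negative-binomial counts
coupled by a Gaussian copula, a hub whose correlations to its neighbors exist
only in the tumor condition, low-count genes, true expression shifts, and
exponential survival linked to a planted high-risk group — so every stage is
testable without any data download.

## Worked example

```python
from lectnet import (SimulationConfig, generate_two_condition_counts,
                     estimate_size_factors, normalize_log2,
                     spearman_matrix, build_differential_network,
                     identify_hubs)

cfg = SimulationConfig(seed=1)  # 39 genes, 145 tumor / 255 control samples,
                                # hub G001 with 8 neighbors at latent rho 0.7
tumor, control, truth = generate_two_condition_counts(cfg)

def prep(mat):
    return normalize_log2(mat, estimate_size_factors(mat))

net = build_differential_network(spearman_matrix(prep(tumor)),
                                 spearman_matrix(prep(control)),
                                 z_threshold=3.0)
hubs = identify_hubs(net, percentile=80)
print(net.n_edges, sorted(hubs.hubs), truth.planted_hubs)
```

prints

```
19 ['G001', 'G003'] {'G001'}
```

— the differential network contains 19 edges (the 8 planted hub–neighbor
links, plus neighbor–neighbor and chance edges), and the degree-percentile
rule recovers the planted hub G001 (G003, one of its neighbors, ties at the
degree cutoff because neighbors inherit correlation through the hub).

The same pipeline is available from the shell:

```bash
lectnet simulate --out sim --seed 1
lectnet run --config run.yaml      # discovery → network → hubs → DE → survival
```

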