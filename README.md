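# ripnet

Size-constrained community detection for gene co-expression networks.

Clusters of co-expressed genes are the working unit of much transcriptome
analysis: they feed gene-set enrichment, attribute construction, and sample
classification. Spectral modularity maximization (Newman's
leading-eigenvector method) finds the number of clusters automatically, but
on real co-expression networks it tends to return a few giant modules that
are too broad to interpret, alongside fragments too small to test for
pathway enrichment. `ripnet` implements **recursive indirect-paths
modularity (RIP-M)**: a merge-and-split engine around spectral modularity
that steers module sizes into a user-specified range — splitting oversized
modules by re-applying the spectral recursion to their subnetworks, and
merging undersized ones by re-clustering their pooled subnetwork with a
power series of the adjacency matrix that rewards indirect connections —
without ever discarding a gene.

## The method

Starting from a Pearson correlation matrix ρ between gene expression
profiles, a network is built by a **hard threshold** (binary adjacency,
A_ij = 1 iff |ρ_ij| ≥ τ) or a **soft threshold** (weighted adjacency,
A_ij = ρ_ij^β for an even power β). Modularity of a bipartition encoded by
s_i ∈ {−1, +1} is

    Q = (1/4m) Σ_ij (A_ij − k_i k_j / 2m) s_i s_j,

with degrees k_i and m = ½ Σ k_i. The dominant eigenvector of the
modularity matrix B_ij = A_ij − k_i k_j/2m, rounded to signs, gives the
binary split; recursion on a subgroup g uses the subgroup matrix
B(g)_ij = B_ij − δ_ij Σ_{k∈g} B_ik, whose zero row sums make per-split
gains ΔQ additive. Recursion stops when ΔQ is no longer positive.

The **indirect-paths generalization (IP-M)** replaces A by the path matrix

    P(n) = A + A² + ⋯ + Aⁿ,

whose entries (for binary A) count walks of length ≤ n between genes, and
computes modularity with degrees taken from P(n). Shared indirect
neighbours thereby pull genes together, which merges small modules.

**RIP-M** combines both in a stack-based engine with a target size range
[minModuleSize, maxModuleSize]: modules above the maximum are pushed back
for further splitting (spectral recursion on the induced subnetwork);
modules below the minimum are pooled and re-clustered with IP-M at
increasing order n = 2, 3, … until the size target or a maximum merge
order is reached; in-range modules are returned. Modules that cannot be
split or merged are returned flagged (`oversized_unsplittable`,
`undersized_unmergeable`, …) rather than dropped.

The package also ships the surrounding study apparatus: block-diagonal
correlation-matrix simulators (uniform and beta noise, homogeneous or
heterogeneous cluster sizes, Higham nearest-positive-definite repair),
Rand-index benchmarking against ground truth with a topological-overlap
(TOM) hierarchical baseline, and module annotation (hub genes,
hypergeometric gene-set enrichment with Benjamini–Hochberg q-values,
pathway-collapsed network export).

## Worked example

Simulate a 200-gene network with 8 planted clusters (within-block
correlations uniform on [0.2, 1], background on [0, 0.8]), threshold at
τ = 0.8 and run RIP-M with a 10–50 size target:

```python
import numpy as np
from ripnet import (SimConfig, RipmConfig, CorrelationMatrix, hard_threshold,
                    replicate_batch, ripm_partition, rand_index,
                    describe_result, hub_genes)

net = next(replicate_batch(SimConfig(n_nodes=200, n_clusters=8, seed=7), 1))
corr = CorrelationMatrix(np.abs(net.corr.values), net.corr.gene_ids, absolute=True)
adj = hard_threshold(corr, 0.8)
result = ripm_partition(adj, RipmConfig(min_module_size=10, max_module_size=50))
print(describe_result(result, hub_genes(adj, result.partition)).to_string(index=False))
print("Rand index vs simulated truth:", rand_index(result.partition, net.true_labels))
```

Output:

```
 module  size     flag hub_gene
      0    25 in_range    g0000
      1    25 in_range    g0045
      2    25 in_range    g0069
      3    25 in_range    g0075
      4    25 in_range    g0107
      5    25 in_range    g0127
      6    25 in_range    g0153
      7    25 in_range    g0186
Rand index vs simulated truth: 1.0
```

All eight planted blocks of 25 genes are recovered exactly (Rand index 1):
at τ = 0.8 no background correlation can survive thresholding, so the
network decomposes into the true blocks and RIP-M finds each one, flagged
`in_range`. Each module's hub is its highest within-module-degree gene.

The same pipeline is available from the shell:

```bash
ripnet simulate --nodes 400 --clusters 10 --reps 1 --seed 7 --out sim/
ripnet cluster --adj adj.tsv --min-size 10 --max-size 50 --out run/
ripnet newman --adj adj.tsv --out labels.tsv
ripnet benchmark --config sweep.yaml --out bench/
ripnet annotate --adj adj.tsv --labels run/labels.tsv --gmt sets.gmt --out ann/
```

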