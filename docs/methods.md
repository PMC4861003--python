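# Methods

This note documents the models and procedures implemented in `ripnet`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the simulation-based tests do and do not
establish about real data.

## Network construction (`graphbuild`)

Expression is a genes × samples matrix; Pearson correlation across
samples gives the gene × gene similarity. Correlation of a constant
profile is undefined, so zero-variance genes are a hard error (naming
the gene) rather than silent NaN; at least 3 samples are required.
Optionally the absolute value |ρ| is taken so activation and repression
links carry the same weight.

Two threshold transformations produce an adjacency matrix:

* hard: A_ij = 1 iff |ρ_ij| ≥ τ, i ≠ j (binary network);
* soft: A_ij = ρ_ij^β with β an even integer ≥ 2 (weighted network;
  even powers remove sign, so odd powers are rejected).

The diagonal is forced to zero in both cases. Self-loops would enter
the degrees k_i = Σ_j A_ij and distort the modularity null model, so no
self-correlation ever reaches a clustering computation.

`filter_transcripts` reduces a transcriptome to its most informative
genes by a rank-sum score, `variance_weight · rank(variance) +
rank(mean)`, keeping the top *n* genes in their original order. The
combination is a documented stand-in for "most variable and most
abundant"; the weight (default 1, dimensionless) shifts emphasis
between the two criteria.

## Spectral modularity (`modcore`)

Modularity of a partition is the observed minus expected (configuration
null) within-module edge weight over total weight; for a bipartition
s ∈ {−1, +1}ⁿ, Q = sᵀB s / 4m with B = A − k kᵀ/2m. The leading
eigenvector of B, rounded to signs, proposes the split; recursion on a
subgroup g uses B(g)_ij = B_ij − δ_ij Σ_{k∈g} B_ik, restricted to g.
Because every B(g) has zero row sums, Q of the trivial single-community
partition is exactly 0 and the final Q equals the sum of accepted split
gains (asserted to 1e−8 in tests).

Numerical and degenerate-input choices:

* A split is accepted iff ΔQ > `deltaQ_tol` (default 1e−10, exposed).
* Eigenvector sign ambiguity (±v) is fixed by making the first
  component of magnitude > 1e−12 positive; entries exactly 0 round to
  +1. Results are therefore bit-reproducible.
* Disconnected groups are split along connected components before any
  eigenvector is computed. Component separation is always a
  positive-gain bipartition, and it sidesteps a real failure mode:
  identical components make the dominant eigenvalue degenerate, and a
  rounded eigenvector from that eigenspace can cut through a component.
  The gain of a component split is still computed from B(g), so gain
  additivity is preserved. (The optional Kernighan–Lin refinement sweep
  of the original spectral method is not implemented.)
* Degree-0 nodes are excluded from the eigen computation and emitted as
  singleton modules tagged `isolated`; they contribute nothing to Q.
  An entirely edgeless network (m = 0) is an error at this layer.
* For subgroups larger than 64 nodes only the top eigenpair is computed
  (`scipy.linalg.eigh` with an index subset); below that a full
  symmetric eigendecomposition is cheaper.

## Indirect paths (`ippaths`)

P(n) = A + A² + ⋯ + Aⁿ. For binary A, entry (i, j) is the number of
walks of length ≤ n between i and j — walks, not simple paths: matrix
powers revisit nodes, and that is the only reading consistent with the
defining sum. P(1) = A exactly, so order-1 indirect-paths modularity is
plain spectral modularity (asserted over 100 random networks).

The diagonal of P(n) (closed walks) is kept during construction but
zeroed before degrees and modularity are computed, consistent with the
no-self-loop convention above; `PathMatrix.as_adjacency` exposes the
flag. On weighted inputs the entries of P(n) can grow geometrically
with n; an optional max-entry normalization is provided purely for
conditioning (Q is invariant to global scaling of the input matrix).

`merge_small_modules` pools undersized modules, restricts the network
to the pooled genes, and re-clusters with indirect-paths modularity at
n = 2, 3, …, `max_merge_order`, stopping as soon as every module
reaches the minimum size. Iteration starts at n = 2 because n = 1 was
already applied upstream. An edgeless pool carries no merge evidence at
any order and is returned as a single `merged-by-default` module.

## The RIP-M engine (`ripm`)

The engine holds a stack of unresolved groups. A popped group is
partitioned by the spectral recursion **on its induced subnetwork** —
degrees and the null model are recomputed locally. This matters: a
module the whole-network recursion refuses to split can reveal
substructure when treated as its own network, which is what lets the
engine decompose giant modules. The resulting modules are triaged by
size:

* above `max_module_size`: back on the stack (a group its own local
  recursion cannot split is finalized `oversized_unsplittable`);
* inside [`min_module_size`, `max_module_size`]: finalized `in_range`;
* below `min_module_size`: into the merge pool, along with isolated
  nodes.

When the stack empties, the pool is merged with `merge_small_modules`
and the merge products re-enter the triage — split only if above the
maximum; in-range products are accepted as-is. Because a merge can
create an oversized module whose split recreates small ones, the merge
phase runs at most `max_rounds` times (default 3); groups still
undersized afterwards are finalized `undersized_unmergeable` (isolated
singletons keep the `isolated` flag). Termination is guaranteed: every
split strictly decreases group size and the merge rounds are bounded.

Defaults: `min_module_size` 10 and `max_module_size` 50 match the
simulation benchmark configuration; `max_merge_order` 5 (the merge loop
rarely needs more than two or three orders in practice);
`deltaQ_tol` 1e−10. The size range is a guideline, not a constraint:
flags record every deviation, and module sizes always sum to the input
gene count — no gene is ever unassigned.

## Simulators (`simulate`)

Both simulators plant clusters as diagonal blocks in a gene × gene
correlation matrix and record true labels.

* Uniform: background entries ~ U(0, r_noise_max), block entries ~
  U(r_signal_min, 1); defaults r_signal_min = 0.2, r_noise_max = 0.8 —
  heavily overlapping signal and noise, deliberately hard. The upper
  triangle is copied to the lower and the diagonal set to 1. The result
  is generally *not* positive definite and is left unrepaired by
  default.
* Beta: block entries ~ Beta(3, 2) (mean 0.6), background ~ Beta(2, 3)
  (mean 0.4) — similar overlap with a softer transition — followed by
  nearest-positive-definite repair by default.

Cluster sizes are homogeneous (equal, remainder spread one per cluster)
or heterogeneous (symmetric Dirichlet(1) proportions scaled to the node
count with a floor of 5 — a stand-in law, since only the qualitative
pattern of variable sizes is specified anywhere). Replicates derive
per-replicate seeds from the master seed through `SeedSequence`
hashing, so adding replicates never perturbs earlier ones.

The nearest-PD projection is the Higham alternating projection with
Dykstra's correction: clip negative eigenvalues, restore the unit
diagonal, repeat until the smallest eigenvalue is ≥ −1e−8 (max 100
iterations, then error). The projection can push off-diagonal entries
marginally outside the generation range; entries are clamped to
[−1, 1], and the simulated matrices are stored as general (not
absolute-valued) correlation matrices for this reason.

A structural property the benchmark leans on: thresholding a uniform
simulation at τ = r_noise_max removes every between-block edge with
probability 1, so the network decomposes into the true blocks and any
sane clusterer recovers them exactly — the exact-recovery regime.

What the simulators do **not** emulate: correlations estimated from
finite samples (matrices are drawn directly, so there is no
estimation noise or sample-size effect), negative correlations,
overlapping or fuzzy module membership, and scale-free degree
structure. Passing benchmarks here demonstrates correct mechanics and
the claimed method ordering under the stated noise models, not
performance on any particular real transcriptome.

## Evaluation (`evaluate`)

Accuracy is the plain Rand index — the fraction of gene pairs on which
two partitions agree — matching the criterion the benchmark design
calls for; the adjusted (chance-corrected) Rand index is reported as a
secondary column. Computation is delegated to scikit-learn's
pair-counting implementation; the test suite checks it against an
explicit O(n²) pair-enumeration oracle.

The TOM baseline assigns similarity
t_ij = (|N₁(i) ∩ N₁(j)| + a_ij)/(min(|N₁(i)|, |N₁(j)|) + 1 − a_ij)
(1 on the diagonal), converts to distance 1 − t, and cuts an
average-linkage dendrogram at a fixed cluster count k. The formula is
count-based, so weighted (soft-threshold) networks are rejected; in
sweeps the baseline is recorded as missing on those cells. In
benchmarks k is set to the true cluster count, which favours the
baseline and makes comparisons against RIP-M conservative. This is a
simplified stand-in for WGCNA-style clustering — dynamic tree cutting,
scale-free threshold selection, and module eigengenes are out of scope.

`sweep_experiment` crosses replicates × thresholds × methods, scores
each run against the simulated truth, and aggregates mean and standard
error per cell. A method failing on a single cell (e.g. an edgeless
network at a high threshold) is recorded as missing rather than
aborting the sweep. Default grids: hard thresholds 0.1–0.9 in steps of
0.1, soft powers {2, 4, 6, 8, 10}.

## Annotation (`annotate`)

Hub genes maximize within-module degree (ties: lexicographically
smallest ID). Gene-set enrichment is the upper-tail hypergeometric
probability P(X ≥ k) for a module of N genes sharing k with a set of n
genes in a universe of M; q-values are Benjamini–Hochberg, computed
jointly across all module × set tests. The universe defaults to the
clustered gene list and is overridable; any reporting cutoff (q < 0.1
is the conventional choice) is applied only at the reporting layer.
The pathway-collapsed network contracts each module to one node
(attributes: gene count, top pathway by smallest p, hub gene) and
weights module–module edges by inter-module gene-edge counts; only
edges in the top-k heaviest of at least one endpoint module are kept
(union semantics), with the pre-filter total preserved for conservation
checks. Gene sets load from standard GMT (tab-separated name,
description, members).

## Reproducibility

Every stochastic component takes an explicit seed; a master seed fans
out to per-component seeds by hashing, so runs are bit-reproducible and
independent of execution order. Outputs are written atomically. The
benchmark problem sizes used by the test suite and the acceptance
script (400-gene networks, 10–20 replicates per cell) are scaled-down
versions of the 100-replicate protocol the simulators default to;
`replicate_batch(config, 100)` reproduces the full-size protocol.
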