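"""Construction of correlation and adjacency matrices from expression data.

A co-expression network starts from a gene x sample expression matrix.
Pearson correlation across samples gives the raw similarity substrate;
a *hard* threshold binarizes ``|rho| >= tau`` into an unweighted network,
while a *soft* threshold raises each correlation to an even power,
keeping a weighted network in which weak correlations are shrunk toward
zero.  Both transformations force the diagonal to zero so that the
network carries no self-loops (self-loops would inflate node degrees in
every downstream modularity computation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "compute_correlation",
    "hard_threshold",
    "soft_threshold",
    "filter_transcripts",
]

_SYM_TOL = 1e-10


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with row/column identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite value for gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}; imputation is not performed"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene Pearson correlation matrix.

    ``absolute=True`` records that ``|rho|`` was taken, so entries live in
    [0, 1] instead of [-1, 1].
    """

    values: np.ndarray
    gene_ids: list[str]
    absolute: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape does not match gene_ids")
        _check_unique(self.gene_ids, "gene")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise ValueError("correlation matrix diagonal must be 1")
        lo = 0.0 if self.absolute else -1.0
        if self.values.min(initial=1.0) < lo - 1e-8 or self.values.max(initial=-1.0) > 1.0 + 1e-8:
            raise ValueError(f"correlation entries outside [{lo}, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class AdjacencyMatrix:
    """Thresholded network: binary (hard threshold) or weighted (soft power).

    Invariants: symmetric, nonnegative, zero diagonal; ``kind='binary'``
    implies entries in {0, 1}.  ``provenance`` records the threshold used.
    """

    values: np.ndarray
    gene_ids: list[str]
    kind: str = "binary"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("adjacency matrix shape does not match gene_ids")
        _check_unique(self.gene_ids, "gene")
        if self.kind not in ("binary", "weighted"):
            raise ValueError(f"kind must be 'binary' or 'weighted', got {self.kind!r}")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("adjacency matrix is not symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 0:
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if self.values.min(initial=0.0) < 0:
            raise ValueError("adjacency entries must be nonnegative")
        if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary adjacency entries must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    def degrees(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def subnetwork(self, idx: np.ndarray | list[int]) -> "AdjacencyMatrix":
        """Induced subnetwork on the given node positions (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return AdjacencyMatrix(
            self.values[np.ix_(idx, idx)],
            [self.gene_ids[i] for i in idx],
            kind=self.kind,
            provenance=self.provenance,
        )


def compute_correlation(expr: ExpressionMatrix, absolute: bool = False) -> CorrelationMatrix:
    """Pearson correlation between every pair of gene profiles.

    Requires >= 2 genes, >= 3 samples, and nonzero variance for every gene
    (constant profiles have undefined correlation and raise, naming the
    offending gene, rather than propagating NaN).
    """
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes to compute correlations")
    if expr.n_samples < 3:
        raise ValueError(f"need at least 3 samples, got {expr.n_samples}")
    variances = expr.values.var(axis=1)
    if np.any(variances == 0):
        gene = expr.gene_ids[int(np.argmax(variances == 0))]
        raise ValueError(f"gene {gene!r} has zero variance across samples")
    corr = np.corrcoef(expr.values)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    if absolute:
        corr = np.abs(corr)
    return CorrelationMatrix(corr, expr.gene_ids, absolute=absolute)


def hard_threshold(corr: CorrelationMatrix, tau: float) -> AdjacencyMatrix:
    """Binary adjacency: edge iff ``|rho_ij| >= tau`` for i != j."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"hard threshold tau must be in [0, 1], got {tau}")
    adj = (np.abs(corr.values) >= tau).astype(float)
    np.fill_diagonal(adj, 0.0)
    return AdjacencyMatrix(adj, corr.gene_ids, kind="binary", provenance=f"hard tau={tau:g}")


def soft_threshold(corr: CorrelationMatrix, power: int) -> AdjacencyMatrix:
    """Weighted adjacency ``rho_ij ** power`` for an even power >= 2.

    Even powers give negative correlations the same weight as positive
    ones (sign removal), which is why odd powers are rejected.
    """
    if power < 2 or power % 2 != 0:
        raise ValueError(
            f"soft-threshold power must be an even integer >= 2 "
            f"(sign removal requires an even power), got {power}"
        )
    adj = corr.values**power
    np.fill_diagonal(adj, 0.0)
    return AdjacencyMatrix(adj, corr.gene_ids, kind="weighted", provenance=f"soft power={power}")


def filter_transcripts(
    expr: ExpressionMatrix, n_keep: int, variance_weight: float = 1.0
) -> ExpressionMatrix:
    """Keep the ``n_keep`` genes with the largest combined variance/abundance.

    Each gene is scored by ``variance_weight * rank(variance) + rank(mean)``
    (average ranks, larger is better); the top ``n_keep`` genes are retained
    in their original order.  The rank-sum combination is this package's
    stand-in for "largest variation and largest read counts"; the weight
    shifts emphasis between the two.
    """
    if n_keep <= 0:
        raise ValueError(f"n_keep must be positive, got {n_keep}")
    if n_keep > expr.n_genes:
        raise ValueError(f"n_keep={n_keep} exceeds the {expr.n_genes} available genes")
    variances = expr.values.var(axis=1)
    means = expr.values.mean(axis=1)
    score = variance_weight * stats.rankdata(variances) + stats.rankdata(means)
    # stable sort on -score keeps original order among exact ties
    order = np.argsort(-score, kind="stable")[:n_keep]
    keep = np.sort(order)
    return ExpressionMatrix(
        expr.values[keep], [expr.gene_ids[i] for i in keep], expr.sample_ids
    )
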