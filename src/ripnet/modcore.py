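"""Newman spectral modularity: matrix, leading-eigenvector splits, recursion.

Modularity of a partition is

    Q = (1/4m) sum_ij (A_ij - k_i k_j / 2m) s_i s_j

for a bipartition encoded as s_i in {-1, +1}, where k_i is the (weighted)
degree of node i and m = (1/2) sum_i k_i.  The modularity matrix
B_ij = A_ij - k_i k_j / 2m has zero row sums, so Q of the trivial
one-community partition is exactly 0.  A bipartition is found by rounding
the dominant eigenvector of B to signs; recursion on a subgroup g uses
the subgroup matrix

    B(g)_ij = B_ij - delta_ij sum_{k in g} B_ik

whose zero row sums make the per-split modularity gains additive: the
final Q equals the sum of accepted deltaQ values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .graphbuild import AdjacencyMatrix

__all__ = [
    "ModularityMatrix",
    "SplitResult",
    "Partition",
    "modularity_matrix",
    "modularity_score",
    "leading_eigenvector_split",
    "subgroup_modularity_matrix",
    "newman_partition",
    "DEFAULT_DELTAQ_TOL",
]

DEFAULT_DELTAQ_TOL = 1e-10


@dataclass
class ModularityMatrix:
    B: np.ndarray
    degrees: np.ndarray
    m: float


@dataclass
class SplitResult:
    """Outcome of one spectral bipartition attempt."""

    s: np.ndarray  # entries in {-1, +1}
    deltaQ: float
    converged: bool

    @property
    def is_split(self) -> bool:
        """True when both sign groups are nonempty."""
        return bool(np.any(self.s > 0) and np.any(self.s < 0))


@dataclass
class Partition:
    """Assignment of every node to exactly one module.

    ``labels`` are integers aligned with ``node_ids``.  ``module_tags``
    optionally annotates labels (e.g. "isolated"); ``split_gains`` records
    the accepted deltaQ of each binary split that produced the partition.
    """

    labels: np.ndarray
    node_ids: list[str]
    method_tag: str = ""
    module_tags: dict[int, str] = field(default_factory=dict)
    split_gains: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.node_ids = list(self.node_ids)
        if self.labels.shape != (len(self.node_ids),):
            raise ValueError("labels must align with node_ids")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))

    def module_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def members(self, label: int) -> list[str]:
        return [g for g, l in zip(self.node_ids, self.labels) if l == label]

    def groups(self) -> dict[int, np.ndarray]:
        """Module label -> node positions."""
        order = np.argsort(self.labels, kind="stable")
        labels, starts = np.unique(self.labels[order], return_index=True)
        splits = np.split(order, starts[1:])
        return dict(zip(labels.tolist(), splits))

    def relabelled(self) -> "Partition":
        """Contiguous labels 0..K-1 in order of first appearance."""
        _, first = np.unique(self.labels, return_index=True)
        old_in_order = self.labels[np.sort(first)]
        mapping = {int(o): i for i, o in enumerate(old_in_order)}
        new = np.array([mapping[int(l)] for l in self.labels])
        tags = {mapping[k]: v for k, v in self.module_tags.items() if k in mapping}
        return Partition(new, self.node_ids, self.method_tag, tags, list(self.split_gains))


def modularity_matrix(A: AdjacencyMatrix) -> ModularityMatrix:
    """B = A - k k^T / 2m with weighted degrees k and m = (1/2) sum k."""
    k = A.degrees()
    m = k.sum() / 2.0
    if m <= 0:
        raise ValueError("no edges at this threshold (m = 0)")
    B = A.values - np.outer(k, k) / (2.0 * m)
    return ModularityMatrix(B=B, degrees=k, m=m)


def modularity_score(A: AdjacencyMatrix, partition: Partition) -> float:
    """Q of an arbitrary partition: (1/2m) sum of B over same-module pairs."""
    if list(partition.node_ids) != list(A.gene_ids):
        raise ValueError("partition nodes do not match the adjacency matrix")
    mm = modularity_matrix(A)
    q = 0.0
    for idx in partition.groups().values():
        q += mm.B[np.ix_(idx, idx)].sum()
    return q / (2.0 * mm.m)


def leading_eigenvector_split(B_sub: np.ndarray, m: float) -> SplitResult:
    """Round the dominant eigenvector of a (subgroup) modularity matrix.

    The eigenvector associated with the most positive eigenvalue is
    dichotomized by sign (entries exactly 0 go to +1); its overall sign is
    fixed by making the first component of magnitude > 1e-12 positive, so
    results are reproducible.  deltaQ = s^T B_sub s / 4m.  A vector whose
    signs do not mix yields no split (deltaQ then carries no usable gain).
    """
    B_sub = np.asarray(B_sub, dtype=float)
    n = B_sub.shape[0]
    if n == 1:
        return SplitResult(s=np.ones(1), deltaQ=0.0, converged=True)
    try:
        if n > 64:
            vals, vecs = scipy.linalg.eigh(B_sub, subset_by_index=(n - 1, n - 1))
            v = vecs[:, 0]
        else:
            vals, vecs = np.linalg.eigh(B_sub)
            v = vecs[:, -1]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - solver failure
        raise RuntimeError(f"eigen-solver failed on a {n}x{n} subgroup matrix") from exc
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        v = -v
    s = np.where(v >= 0, 1.0, -1.0)
    deltaQ = float(s @ B_sub @ s) / (4.0 * m)
    return SplitResult(s=s, deltaQ=deltaQ, converged=True)


def subgroup_modularity_matrix(B: np.ndarray, g: np.ndarray | list[int]) -> np.ndarray:
    """Restrict B to group g and re-zero the row sums.

    B(g)_ij = B_ij - delta_ij sum_{k in g} B_ik for i, j in g; with g the
    full node set the correction vanishes because B already has zero rows.
    """
    g = np.asarray(g, dtype=int)
    if g.size == 0:
        raise ValueError("subgroup must be nonempty")
    Bg = np.array(B[np.ix_(g, g)])
    Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
    return Bg


def newman_partition(
    A: AdjacencyMatrix, deltaQ_tol: float = DEFAULT_DELTAQ_TOL
) -> Partition:
    """Full recursive leading-eigenvector partition of a network.

    Degree-0 nodes are excluded from the spectral computation and emitted
    as singleton modules tagged "isolated" (they contribute nothing to Q).
    A disconnected group is first split along its connected components
    (always a positive-gain bipartition, and immune to the eigenvector
    degeneracy that identical components create); otherwise a group is
    split only while the best spectral bipartition gains more than
    ``deltaQ_tol``.  Accepted gains are recorded in ``split_gains``.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    k = A.degrees()
    isolated = np.flatnonzero(k == 0)
    core = np.flatnonzero(k > 0)
    if core.size == 0:
        raise ValueError("no edges at this threshold (m = 0)")

    core_adj = A.subnetwork(core)
    mm = modularity_matrix(core_adj)

    final_groups: list[np.ndarray] = []
    gains: list[float] = []
    stack: list[np.ndarray] = [np.arange(core.size)]
    while stack:
        g = stack.pop()
        if g.size <= 1:
            final_groups.append(g)
            continue
        sub = core_adj.values[np.ix_(g, g)]
        n_comp, comp = connected_components(csr_matrix(sub), directed=False)
        Bg = subgroup_modularity_matrix(mm.B, g)
        if n_comp > 1:
            s = np.where(comp == comp[0], 1.0, -1.0)
            dq = float(s @ Bg @ s) / (4.0 * mm.m)
            res = SplitResult(s=s, deltaQ=dq, converged=True)
        else:
            res = leading_eigenvector_split(Bg, mm.m)
        if res.is_split and res.deltaQ > deltaQ_tol:
            gains.append(res.deltaQ)
            stack.append(g[res.s > 0])
            stack.append(g[res.s < 0])
        else:
            final_groups.append(g)

    labels = np.empty(A.n_nodes, dtype=int)
    tags: dict[int, str] = {}
    next_label = 0
    for g in final_groups:
        labels[core[g]] = next_label
        next_label += 1
    for i in isolated:
        labels[i] = next_label
        tags[next_label] = "isolated"
        next_label += 1

    part = Partition(
        labels, A.gene_ids, method_tag="newman", module_tags=tags, split_gains=gains
    )
    return part.relabelled()
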