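"""Clustering accuracy scoring and the threshold-sweep benchmark.

Accuracy against the simulated ground truth is the Rand index: the
fraction of node pairs on which two partitions agree (together in both,
or apart in both).  The adjusted Rand index is reported alongside as a
chance-corrected secondary metric.  A simplified WGCNA-style baseline is
included: topological-overlap (TOM) similarity

    t_ij = (|N1(i) & N1(j)| + a_ij) / (min(|N1(i)|, |N1(j)|) + 1 - a_ij)

turned into a distance 1 - t and cut by average-linkage hierarchical
clustering at a fixed cluster count (the dynamic tree cut of full WGCNA
is out of scope here, so the baseline is given the true cluster count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn import metrics as _skm

from .graphbuild import AdjacencyMatrix, CorrelationMatrix, hard_threshold, soft_threshold
from .ippaths import ipm_partition
from .modcore import Partition, newman_partition
from .ripm import RipmConfig, RipmResult, ripm_partition
from .simulate import SimConfig, replicate_batch

__all__ = [
    "TomMatrix",
    "SweepResult",
    "rand_index",
    "adjusted_rand",
    "tom_similarity",
    "tom_baseline_cluster",
    "sweep_experiment",
]


def _aligned_labels(p1: Partition, p2: Partition) -> tuple[np.ndarray, np.ndarray]:
    if set(p1.node_ids) != set(p2.node_ids):
        raise ValueError("partitions are over different node sets")
    if p1.node_ids == p2.node_ids:
        return p1.labels, p2.labels
    pos = {g: i for i, g in enumerate(p2.node_ids)}
    order = [pos[g] for g in p1.node_ids]
    return p1.labels, p2.labels[order]


def rand_index(p1: Partition, p2: Partition) -> float:
    """Plain (unadjusted) Rand index between two partitions of one node set."""
    a, b = _aligned_labels(p1, p2)
    return float(_skm.rand_score(a, b))


def adjusted_rand(p1: Partition, p2: Partition) -> float:
    """Chance-corrected Rand index (can be negative)."""
    a, b = _aligned_labels(p1, p2)
    return float(_skm.adjusted_rand_score(a, b))


@dataclass
class TomMatrix:
    t: np.ndarray
    gene_ids: list[str]


def tom_similarity(A: AdjacencyMatrix) -> TomMatrix:
    """Topological overlap similarity of a *binary* adjacency matrix."""
    if A.kind != "binary":
        raise ValueError("TOM similarity is defined here for binary adjacency only")
    a = A.values
    shared = a @ a  # shared-neighbour counts
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    t = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(t, 1.0)
    return TomMatrix(t=t, gene_ids=list(A.gene_ids))


def tom_baseline_cluster(A: AdjacencyMatrix, k: int) -> Partition:
    """Average-linkage clustering of TOM distance 1 - t, cut at k clusters."""
    n = A.n_nodes
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    tom = tom_similarity(A)
    dist = 1.0 - tom.t
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    return Partition(labels, A.gene_ids, method_tag="tom")


@dataclass
class SweepResult:
    """Long-format per-replicate scores and the per-cell aggregate."""

    records: pd.DataFrame  # method, threshold, replicate, rand, ari
    aggregate: pd.DataFrame  # method, threshold, mean_rand, se_rand, n

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "SweepResult":
        grp = records.groupby(["method", "threshold"])["rand"]
        agg = grp.agg(
            mean_rand="mean",
            se_rand=lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
            n="count",
        ).reset_index()
        return cls(records=records, aggregate=agg)

    def mean_rand(self, method: str, threshold: float) -> float:
        sel = self.aggregate[
            (self.aggregate["method"] == method)
            & (np.isclose(self.aggregate["threshold"], threshold))
        ]
        return float(sel["mean_rand"].iloc[0])


def _run_method(
    method: str,
    adj: AdjacencyMatrix,
    ripm_config: RipmConfig,
    ipm_order: int,
    true_k: int,
) -> Partition:
    if method == "newman":
        return newman_partition(adj, deltaQ_tol=ripm_config.deltaQ_tol)
    if method == "ipm":
        return ipm_partition(adj, ipm_order, deltaQ_tol=ripm_config.deltaQ_tol)
    if method == "ripm":
        res: RipmResult = ripm_partition(adj, ripm_config)
        return res.partition
    if method == "tom":
        return tom_baseline_cluster(adj, true_k)
    raise ValueError(f"unknown method {method!r}")


def sweep_experiment(
    sim_config: SimConfig,
    methods: list[str],
    threshold_kind: str,
    threshold_values: list[float],
    n_replicates: int,
    ripm_config: RipmConfig | None = None,
    ipm_order: int = 2,
) -> SweepResult:
    """Benchmark clustering methods over a threshold grid on replicates.

    For every replicate and threshold the correlation matrix is thresholded
    (hard tau or soft even power of |rho|), each method is run, and its
    Rand index / ARI against the simulated truth is recorded.  A method
    failing on one cell (e.g. an edgeless network at a high threshold, or
    TOM requested on a weighted network) is recorded as NaN rather than
    aborting the sweep; only all cells failing is an error.
    """
    if threshold_kind not in ("hard", "soft"):
        raise ValueError(f"threshold_kind must be 'hard' or 'soft', got {threshold_kind!r}")
    ripm_config = ripm_config or RipmConfig()
    rows = []
    for rep, net in enumerate(replicate_batch(sim_config, n_replicates)):
        corr_abs = CorrelationMatrix(
            np.abs(net.corr.values), net.corr.gene_ids, absolute=True
        )
        true_k = net.true_labels.n_modules
        for thr in threshold_values:
            if threshold_kind == "hard":
                adj = hard_threshold(corr_abs, thr)
            else:
                adj = soft_threshold(corr_abs, int(thr))
            for method in methods:
                try:
                    part = _run_method(method, adj, ripm_config, ipm_order, true_k)
                    rows.append({
                        "method": method, "threshold": thr, "replicate": rep,
                        "rand": rand_index(part, net.true_labels),
                        "ari": adjusted_rand(part, net.true_labels),
                        "n_modules": part.n_modules,
                    })
                except (ValueError, RuntimeError):
                    rows.append({
                        "method": method, "threshold": thr, "replicate": rep,
                        "rand": np.nan, "ari": np.nan, "n_modules": 0,
                    })
    records = pd.DataFrame(rows)
    if records["rand"].isna().all():
        raise RuntimeError("every method failed on every replicate/threshold cell")
    ok = records.dropna(subset=["rand"])
    return SweepResult.from_records(ok)
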