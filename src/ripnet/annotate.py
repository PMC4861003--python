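"""Biological annotation of modules: hubs, enrichment, collapsed network.

Modules are summarized by their hub gene (highest within-module degree),
tested for gene-set over-representation with the upper-tail
hypergeometric probability (Benjamini-Hochberg q-values across all
module x set tests jointly), and exported as a pathway-collapsed graph
in which each module becomes one node and inter-module edge counts
become edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graphbuild import AdjacencyMatrix
from .modcore import Partition

__all__ = [
    "GeneSetCollection",
    "CollapsedGraph",
    "hub_genes",
    "hypergeometric_enrichment",
    "top_pathway_labels",
    "collapse_network",
    "read_gmt",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways); genes within a set are unique."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Load a GMT file (tab-separated: set name, description, genes...).

    Duplicate genes within a set are stored once; lines with no genes are
    dropped with a warning; malformed lines raise with their line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed GMT line {lineno} (need name + description)")
            name = parts[0].strip()
            if not name:
                raise ValueError(f"{path}: empty set name on line {lineno}")
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} on line {lineno}")
            genes = list(dict.fromkeys(g.strip() for g in parts[2:] if g.strip()))
            if not genes:
                logger.warning("dropping empty gene set %r (line %d)", name, lineno)
                continue
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def hub_genes(A: AdjacencyMatrix, partition: Partition) -> dict[int, str]:
    """Per module, the gene with the highest within-module degree.

    Degree counts only edges to genes of the same module; ties go to the
    lexicographically smallest gene ID.
    """
    if list(partition.node_ids) != list(A.gene_ids):
        raise ValueError("partition nodes do not match the adjacency matrix")
    hubs: dict[int, str] = {}
    for label, idx in partition.groups().items():
        sub = A.values[np.ix_(idx, idx)]
        deg = sub.sum(axis=1)
        best = max(
            range(len(idx)),
            key=lambda i: (deg[i], _NegStr(A.gene_ids[idx[i]])),
        )
        hubs[label] = A.gene_ids[idx[best]]
    return hubs


class _NegStr(str):
    """Reverses string comparison so max() picks the lexicographic minimum."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def hypergeometric_enrichment(
    partition: Partition,
    genesets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every module x gene set.

    For a universe of size M, a set with n members in the universe, and a
    module of N genes sharing k with the set, the p-value is
    P(X >= k) under sampling N genes without replacement.  q-values are
    Benjamini-Hochberg, computed jointly across all tests; no cutoff is
    applied here — filtering (e.g. q < 0.1) belongs to the reporting layer.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    missing = set(partition.node_ids) - universe_set
    if missing:
        raise ValueError(
            f"{len(missing)} partition genes absent from the universe, "
            f"e.g. {sorted(missing)[:3]}"
        )
    M = len(universe_set)
    rows = []
    for label in sorted(partition.module_sizes()):
        module = set(partition.members(label))
        N = len(module)
        for name in sorted(genesets.sets):
            in_universe = universe_set.intersection(genesets.sets[name])
            n = len(in_universe)
            if n == 0:
                continue
            k = len(module & in_universe)
            p = float(stats.hypergeom.sf(k - 1, M, n, N))
            rows.append({
                "module_label": label,
                "set_name": name,
                "overlap_count": k,
                "module_size": N,
                "set_size_in_universe": n,
                "universe_size": M,
                "p_value": min(p, 1.0),
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["q_value"] = pd.Series(dtype=float)
    return table


def top_pathway_labels(enrichment: pd.DataFrame) -> dict[int, str]:
    """Per module, the gene set with the smallest p-value.

    Ties break to the lexicographically smaller set name; modules with no
    tested set are labelled "unannotated" by callers that know the module
    list (this function only sees tested modules).
    """
    if enrichment.empty:
        raise ValueError("enrichment table is empty")
    best: dict[int, str] = {}
    ordered = enrichment.sort_values(["module_label", "p_value", "set_name"])
    for label, grp in ordered.groupby("module_label"):
        best[int(label)] = str(grp["set_name"].iloc[0])
    return best


def module_pathway_labels(
    partition: Partition, enrichment: pd.DataFrame
) -> dict[int, str]:
    """Top pathway per module, "unannotated" for untested modules."""
    best = top_pathway_labels(enrichment) if len(enrichment) else {}
    return {
        label: best.get(label, "unannotated")
        for label in sorted(partition.module_sizes())
    }


@dataclass
class CollapsedGraph:
    """Module-level summary graph: one node per module, weighted edges.

    ``edges`` hold inter-module gene-edge counts after per-module top-k
    retention; ``total_between_edges`` preserves the pre-filter sum for
    conservation checks.
    """

    nodes: list[dict]
    edges: list[tuple[int, int, int]]
    total_between_edges: int = 0

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        for node in self.nodes:
            G.add_node(node["module_label"], **{k: v for k, v in node.items()
                                                if k != "module_label"})
        for a, b, w in self.edges:
            G.add_edge(a, b, weight=int(w))
        return G

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("module_a\tmodule_b\tweight\n")
            for a, b, w in self.edges:
                fh.write(f"{a}\t{b}\t{w}\n")


def collapse_network(
    A: AdjacencyMatrix,
    partition: Partition,
    labels: dict[int, str] | None = None,
    top_k: int = 5,
    hub_by_label: dict[int, str] | None = None,
) -> CollapsedGraph:
    """Collapse genes of each module into one node; count inter-module edges.

    Edge weight between two modules is the number of gene-level adjacency
    edges connecting them (each undirected gene pair once).  Only edges in
    the top-``top_k`` heaviest of at least one endpoint module are retained,
    mirroring a "top five connections per module" display rule.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if list(partition.node_ids) != list(A.gene_ids):
        raise ValueError("partition nodes do not match the adjacency matrix")
    groups = partition.groups()
    module_labels = sorted(groups)
    present = (A.values != 0).astype(float)
    # indicator matrix (modules x genes) -> inter-module edge counts
    ind = np.zeros((len(module_labels), A.n_nodes))
    for row, lab in enumerate(module_labels):
        ind[row, groups[lab]] = 1.0
    counts = ind @ present @ ind.T
    counts = np.round(counts).astype(int)

    weights: dict[tuple[int, int], int] = {}
    for i, la in enumerate(module_labels):
        for j in range(i + 1, len(module_labels)):
            if counts[i, j] > 0:
                weights[(la, module_labels[j])] = int(counts[i, j])
    total = sum(weights.values())

    keep: set[tuple[int, int]] = set()
    for lab in module_labels:
        incident = [(pair, w) for pair, w in weights.items() if lab in pair]
        incident.sort(key=lambda pw: (-pw[1], pw[0]))
        keep.update(pair for pair, _ in incident[:top_k])

    labels = labels or {}
    hub_by_label = hub_by_label or {}
    nodes = [
        {
            "module_label": lab,
            "gene_count": int(len(groups[lab])),
            "top_pathway": labels.get(lab, "unannotated"),
            "hub_gene": hub_by_label.get(lab, ""),
        }
        for lab in module_labels
    ]
    edges = sorted((a, b, weights[(a, b)]) for (a, b) in keep)
    return CollapsedGraph(nodes=nodes, edges=edges, total_between_edges=total)
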