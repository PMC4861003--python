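"""RIP-M: recursive merge/split engine targeting a module-size range.

The engine maintains a stack of unresolved node groups.  A popped group
is partitioned by the spectral modularity recursion *on its induced
subnetwork* — degrees and the null model are recomputed locally, which
is what lets an oversized module reveal substructure that the global
recursion, with its whole-network null model, has already stopped
resolving.  The resulting modules are triaged by size: modules inside
[``min_module_size``, ``max_module_size``] are finalized; oversized
modules go back on the stack for further local splitting (a module the
local recursion cannot split is finalized ``oversized_unsplittable``);
undersized modules are pooled and re-clustered with indirect-paths
modularity at increasing power-series order, after which the merge
products re-enter the triage.  The size range is a guideline, not a
hard rule: groups that cannot be split or merged are returned, flagged,
rather than dropped, so every input gene appears in exactly one module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .graphbuild import AdjacencyMatrix
from .ippaths import merge_small_modules
from .modcore import DEFAULT_DELTAQ_TOL, Partition, newman_partition

__all__ = ["RipmConfig", "RipmResult", "ripm_partition", "describe_result"]

FLAGS = (
    "in_range",
    "oversized_unsplittable",
    "undersized_unmergeable",
    "merged-by-default",
    "isolated",
)


@dataclass
class RipmConfig:
    """Parameters of the RIP-M engine.

    min/max module size define the target range; ``max_merge_order`` caps
    the power-series order used when consolidating undersized modules;
    ``max_rounds`` bounds the number of merge phases so alternating
    merge/split cannot oscillate forever.  ``hard_tau``/``soft_power``
    describe the thresholding applied upstream when starting from a
    correlation matrix (exactly one may be set).
    """

    min_module_size: int = 10
    max_module_size: int = 50
    max_merge_order: int = 5
    deltaQ_tol: float = DEFAULT_DELTAQ_TOL
    max_rounds: int = 3
    random_seed: int = 0
    hard_tau: float | None = None
    soft_power: int | None = None

    def __post_init__(self) -> None:
        if self.min_module_size < 1 or self.max_module_size < 1:
            raise ValueError("module sizes must be positive")
        if self.min_module_size > self.max_module_size:
            raise ValueError(
                f"min_module_size={self.min_module_size} exceeds "
                f"max_module_size={self.max_module_size}"
            )
        if self.max_merge_order < 2:
            raise ValueError("max_merge_order must be >= 2")
        if self.hard_tau is not None and self.soft_power is not None:
            raise ValueError("specify at most one of hard_tau / soft_power")


@dataclass
class RipmResult:
    """Partition plus per-module flags and the ordered split/merge trace."""

    partition: Partition
    flags: dict[int, str]
    trace: list[dict[str, Any]] = field(default_factory=list)

    @property
    def n_modules(self) -> int:
        return self.partition.n_modules

    def modules_with_flag(self, flag: str) -> list[int]:
        return [label for label, f in self.flags.items() if f == flag]


def _local_modules(
    A: AdjacencyMatrix, g: np.ndarray, tol: float
) -> tuple[list[np.ndarray], list[np.ndarray], list[float]]:
    """Spectral recursion on the induced subnetwork of group g.

    Returns (modules, isolated singletons, accepted local deltaQ gains),
    all in global node positions.  An edgeless group yields no modules —
    every node comes back isolated.
    """
    sub = A.subnetwork(g)
    if sub.values.sum() == 0:
        return [], [np.array([i]) for i in g], []
    part = newman_partition(sub, deltaQ_tol=tol)
    modules, singles = [], []
    for label, idx in part.groups().items():
        nodes = g[idx]
        if part.module_tags.get(label) == "isolated":
            singles.append(nodes)
        else:
            modules.append(nodes)
    return modules, singles, [float(x) for x in part.split_gains]


def ripm_partition(A: AdjacencyMatrix, config: RipmConfig) -> RipmResult:
    """Run the full RIP-M merge/split recursion on an adjacency matrix.

    Every node of ``A`` ends up in exactly one module; each module carries
    exactly one flag describing how it was finalized.  The trace records
    every local partitioning pass (with its modularity gains) and merge
    phase (with the path order used) in execution order.
    """
    if A.n_nodes == 0:
        raise ValueError("empty network")
    lo, hi = config.min_module_size, config.max_module_size
    degrees = A.degrees()

    trace: list[dict[str, Any]] = []
    final: list[tuple[np.ndarray, str]] = []  # (global node positions, flag)
    pool: list[np.ndarray] = []

    def finalize(g: np.ndarray, flag: str) -> None:
        final.append((g, flag))
        trace.append({"event": "finalize", "size": int(g.size), "flag": flag})

    def resolve(groups: list[np.ndarray]) -> None:
        """Partition each group with the local spectral recursion, then
        triage the resulting modules by size."""
        stack = list(groups)
        while stack:
            g = stack.pop()
            modules, singles, gains = _local_modules(A, g, config.deltaQ_tol)
            pool.extend(singles)
            if len(modules) > 1:
                trace.append({"event": "split", "group_size": int(g.size),
                              "module_sizes": sorted(int(m.size) for m in modules),
                              "deltaQ_gains": gains})
            for mod in modules:
                if mod.size > hi:
                    if len(modules) == 1 and not singles:
                        # the local recursion could not break this group
                        finalize(mod, "oversized_unsplittable")
                    else:
                        stack.append(mod)
                elif mod.size >= lo:
                    finalize(mod, "in_range")
                else:
                    pool.append(mod)

    resolve([np.arange(A.n_nodes)])

    rounds = 0
    pos_of = {gid: i for i, gid in enumerate(A.gene_ids)}
    while pool:
        if rounds >= config.max_rounds:
            for g in pool:
                flag = ("isolated" if g.size == 1 and degrees[g[0]] == 0
                        else "undersized_unmergeable")
                final.append((g, flag))
                trace.append({"event": "finalize", "size": int(g.size), "flag": flag})
            pool = []
            break
        rounds += 1
        pooled_nodes = [A.gene_ids[i] for g in pool for i in g]
        pool = []
        merge = merge_small_modules(
            A, pooled_nodes, lo, config.max_merge_order, config.deltaQ_tol
        )
        trace.append({"event": "merge", "pool_size": len(pooled_nodes),
                      "order": merge.order_used,
                      "n_modules": len(merge.modules),
                      "merged_by_default": bool(merge.merged_by_default)})
        if merge.merged_by_default:
            g = np.array([pos_of[gid] for gid in merge.modules[0]])
            flag = "isolated" if g.size == 1 and degrees[g[0]] == 0 else "merged-by-default"
            finalize(g, flag)
            continue
        # merge products re-enter the size triage: splitting only applies
        # above the max size, so an in-range product is accepted as-is
        for mod in merge.modules:
            g = np.array([pos_of[gid] for gid in mod])
            if g.size > hi:
                resolve([g])
            elif g.size >= lo:
                finalize(g, "in_range")
            else:
                pool.append(g)

    labels = np.full(A.n_nodes, -1, dtype=int)
    flags: dict[int, str] = {}
    for label, (g, flag) in enumerate(final):
        labels[g] = label
        flags[label] = flag
    if np.any(labels < 0):  # pragma: no cover - conservation guard
        raise AssertionError("RIP-M dropped nodes; this is a bug")

    gains = [dq for t in trace if t["event"] == "split" for dq in t["deltaQ_gains"]]
    partition = Partition(
        labels, A.gene_ids, method_tag="ripm",
        module_tags={l: f for l, f in flags.items() if f != "in_range"},
        split_gains=gains,
    )
    return RipmResult(partition=partition, flags=flags, trace=trace)


def describe_result(result: RipmResult, hub_by_label: dict[int, str] | None = None):
    """Per-module summary table: label, size, flag, optional hub gene.

    Returns a pandas DataFrame sorted by module label, with the number of
    accepted local partitioning passes in ``DataFrame.attrs['n_splits']``.
    """
    import pandas as pd

    sizes = result.partition.module_sizes()
    rows = []
    for label in sorted(sizes):
        rows.append({
            "module": label,
            "size": sizes[label],
            "flag": result.flags.get(label, "in_range"),
            "hub_gene": (hub_by_label or {}).get(label, ""),
        })
    df = pd.DataFrame(rows, columns=["module", "size", "flag", "hub_gene"])
    df.attrs["n_splits"] = sum(1 for t in result.trace if t["event"] == "split")
    return df
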