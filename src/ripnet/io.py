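"""Readers and writers for expression, matrix, and label files (TSV/CSV)."""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .graphbuild import AdjacencyMatrix, CorrelationMatrix, ExpressionMatrix
from .modcore import Partition

__all__ = [
    "read_expression",
    "read_matrix",
    "write_matrix",
    "read_correlation",
    "read_adjacency",
    "write_labels",
    "read_labels",
]

_ASYM_TOL = 1e-8


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path) -> ExpressionMatrix:
    """Genes as rows, first column gene IDs, header row of sample IDs."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(values, [str(g) for g in df.index], [str(s) for s in df.columns])


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Labeled square symmetric matrix from TSV/CSV with matching row/col IDs.

    Asymmetry up to 1e-8 is silently averaged away; larger asymmetry, ragged
    rows, duplicate IDs or non-numeric cells are errors.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    rows = [str(g) for g in df.index]
    cols = [str(g) for g in df.columns]
    if len(set(rows)) != len(rows):
        dup = next(g for i, g in enumerate(rows) if g in rows[:i])
        raise ValueError(f"{path}: duplicate id {dup!r}")
    if set(rows) != set(cols):
        raise ValueError(f"{path}: row and column id sets differ")
    df = df.loc[:, rows]  # align column order to rows
    try:
        M = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric matrix cell ({exc})") from exc
    if not np.all(np.isfinite(M)):
        i, j = np.argwhere(~np.isfinite(M))[0]
        raise ValueError(f"{path}: non-finite cell at row {rows[i]!r}, column {rows[j]!r}")
    asym = np.abs(M - M.T).max(initial=0.0)
    if asym > _ASYM_TOL:
        raise ValueError(f"{path}: matrix asymmetry {asym:.3g} exceeds tolerance {_ASYM_TOL}")
    return (M + M.T) / 2.0, rows


def write_matrix(values: np.ndarray, gene_ids: list[str], path) -> None:
    df = pd.DataFrame(values, index=gene_ids, columns=gene_ids)
    _atomic_write(path, df.to_csv(sep=_sep_for(path)))


def read_correlation(path, absolute: bool | None = None) -> CorrelationMatrix:
    M, ids = read_matrix(path)
    np.fill_diagonal(M, 1.0)
    if absolute is None:
        absolute = bool(M.min() >= 0.0)
    return CorrelationMatrix(M, ids, absolute=absolute)


def read_adjacency(path) -> AdjacencyMatrix:
    M, ids = read_matrix(path)
    np.fill_diagonal(M, 0.0)
    kind = "binary" if np.isin(M, (0.0, 1.0)).all() else "weighted"
    return AdjacencyMatrix(M, ids, kind=kind, provenance=f"loaded from {path}")


def write_labels(partition: Partition, path) -> None:
    """Two-column TSV (gene_id, module_label); atomic overwrite."""
    lines = ["gene_id\tmodule_label"]
    lines += [f"{g}\t{int(l)}" for g, l in zip(partition.node_ids, partition.labels)]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_labels(path, universe: list[str] | None = None) -> Partition:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty label file")
    if list(df.columns[:2]) != ["gene_id", "module_label"]:
        raise ValueError(f"{path}: expected columns gene_id, module_label")
    genes = [str(g) for g in df["gene_id"]]
    if universe is not None:
        unknown = set(genes) - set(universe)
        if unknown:
            raise ValueError(f"{path}: unknown gene(s) {sorted(unknown)[:3]}")
    return Partition(df["module_label"].to_numpy(dtype=int), genes, method_tag="loaded")


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
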