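"""Ground-truth co-expression network simulators.

Both strategies plant clusters as blocks on the diagonal of a gene x gene
correlation matrix over a noisy background and record the true labels:

* **uniform** — background entries ~ U(0, r_noise_max), within-block
  entries ~ U(r_signal_min, 1).  The default parameters
  (r_signal_min = 0.2, r_noise_max = 0.8) overlap heavily, making the
  clusters deliberately hard to resolve.  The matrix is symmetrized and
  given a unit diagonal but is generally *not* positive definite, and is
  left that way by default.
* **beta** — within-block entries ~ Beta(3, 2) (mean 0.6), background ~
  Beta(2, 3) (mean 0.4): a similar signal/noise overlap with a softer
  transition.  Here the matrix *is* repaired to the nearest positive
  semidefinite correlation matrix (Higham alternating projection) by
  default.

Cluster sizes are homogeneous (equal, remainder spread one-per-cluster)
or heterogeneous (Dirichlet-weighted with a floor, emulating variable
real-data module sizes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .graphbuild import CorrelationMatrix
from .modcore import Partition

__all__ = [
    "SimConfig",
    "SimulatedNetwork",
    "make_cluster_sizes",
    "simulate_uniform",
    "simulate_beta",
    "simulate_network",
    "nearest_positive_definite",
    "replicate_batch",
    "derive_seed",
]

_HET_MIN_SIZE = 5


def derive_seed(master_seed: int, *keys: int | str) -> int:
    """Deterministic child seed < 2**31 from a master seed and key path."""
    entropy = [int(master_seed)] + [
        k if isinstance(k, int) else int.from_bytes(str(k).encode(), "little") % (2**32)
        for k in keys
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@dataclass
class SimConfig:
    """Parameters of one simulated network."""

    n_nodes: int = 400
    n_clusters: int = 10
    size_mode: str = "homogeneous"  # or "heterogeneous"
    noise_model: str = "uniform"  # or "beta"
    r_signal_min: float = 0.2
    r_noise_max: float = 0.8
    beta_signal: tuple[float, float] = (3.0, 2.0)
    beta_noise: tuple[float, float] = (2.0, 3.0)
    force_pd: bool | None = None  # None -> per noise model: uniform no, beta yes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_nodes < self.n_clusters:
            raise ValueError("need 1 <= n_clusters <= n_nodes")
        if self.size_mode not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown size_mode {self.size_mode!r}")
        if self.noise_model not in ("uniform", "beta"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not (0 < self.r_signal_min < 1 and 0 < self.r_noise_max < 1):
            raise ValueError("r_signal_min and r_noise_max must be in (0, 1)")

    @property
    def apply_pd(self) -> bool:
        if self.force_pd is None:
            return self.noise_model == "beta"
        return self.force_pd


@dataclass
class SimulatedNetwork:
    corr: CorrelationMatrix
    true_labels: Partition
    config: SimConfig


def make_cluster_sizes(
    n_nodes: int, n_clusters: int, size_mode: str, seed: int = 0
) -> list[int]:
    """Cluster sizes summing to n_nodes.

    Homogeneous: floor(n/k) per cluster, remainder spread one-per-cluster.
    Heterogeneous: proportions drawn from a symmetric Dirichlet(1) over the
    clusters, scaled to n_nodes, with a floor of 5 nodes per cluster.
    """
    if size_mode not in ("homogeneous", "heterogeneous"):
        raise ValueError(f"unknown size_mode {size_mode!r}")
    min_per = 1 if size_mode == "homogeneous" else min(_HET_MIN_SIZE, n_nodes // n_clusters)
    if n_clusters * max(min_per, 2 if size_mode == "heterogeneous" else 1) > n_nodes:
        raise ValueError(
            f"{n_clusters} clusters do not fit in {n_nodes} nodes ({size_mode})"
        )
    if size_mode == "homogeneous":
        base, rem = divmod(n_nodes, n_clusters)
        return [base + (1 if i < rem else 0) for i in range(n_clusters)]
    rng = np.random.default_rng(seed)
    floor = max(min_per, 2)
    free = n_nodes - floor * n_clusters
    w = rng.dirichlet(np.ones(n_clusters))
    extra = np.floor(w * free).astype(int)
    short = free - extra.sum()
    # give leftover nodes to the clusters with the largest fractional parts
    frac_order = np.argsort(-(w * free - extra), kind="stable")
    for i in range(short):
        extra[frac_order[i % n_clusters]] += 1
    sizes = (floor + extra).tolist()
    assert sum(sizes) == n_nodes
    return sizes


def _block_slices(sizes: list[int]) -> list[slice]:
    offs = np.concatenate([[0], np.cumsum(sizes)])
    return [slice(int(a), int(b)) for a, b in zip(offs[:-1], offs[1:])]


def _symmetrize_upper(M: np.ndarray) -> np.ndarray:
    """Copy the upper triangle onto the lower and set a unit diagonal."""
    out = np.triu(M, k=1)
    out = out + out.T
    np.fill_diagonal(out, 1.0)
    return out


def _labels(sizes: list[int], n_nodes: int) -> np.ndarray:
    return np.repeat(np.arange(len(sizes)), sizes)


def _assemble(config: SimConfig, noise: np.ndarray, signal_blocks: list[np.ndarray],
              sizes: list[int]) -> SimulatedNetwork:
    M = noise
    for sl, blk in zip(_block_slices(sizes), signal_blocks):
        M[sl, sl] = blk
    M = _symmetrize_upper(M)
    if config.apply_pd:
        M = nearest_positive_definite(M)
        M = np.clip(M, -1.0, 1.0)
        np.fill_diagonal(M, 1.0)
    gene_ids = [f"g{i:04d}" for i in range(config.n_nodes)]
    corr = CorrelationMatrix(M, gene_ids, absolute=False)
    labels = Partition(_labels(sizes, config.n_nodes), gene_ids, method_tag="truth")
    return SimulatedNetwork(corr=corr, true_labels=labels, config=config)


def simulate_uniform(config: SimConfig) -> SimulatedNetwork:
    """Uniform-noise block simulation (see module docstring)."""
    if config.noise_model != "uniform":
        raise ValueError("config.noise_model must be 'uniform'")
    rng = np.random.default_rng(config.seed)
    sizes = make_cluster_sizes(
        config.n_nodes, config.n_clusters, config.size_mode, seed=derive_seed(config.seed, "sizes")
    )
    n = config.n_nodes
    noise = rng.uniform(0.0, config.r_noise_max, size=(n, n))
    blocks = [rng.uniform(config.r_signal_min, 1.0, size=(s, s)) for s in sizes]
    return _assemble(config, noise, blocks, sizes)


def simulate_beta(config: SimConfig) -> SimulatedNetwork:
    """Beta-noise block simulation (see module docstring)."""
    if config.noise_model != "beta":
        raise ValueError("config.noise_model must be 'beta'")
    rng = np.random.default_rng(config.seed)
    sizes = make_cluster_sizes(
        config.n_nodes, config.n_clusters, config.size_mode, seed=derive_seed(config.seed, "sizes")
    )
    n = config.n_nodes
    a_n, b_n = config.beta_noise
    a_s, b_s = config.beta_signal
    noise = rng.beta(a_n, b_n, size=(n, n))
    blocks = [rng.beta(a_s, b_s, size=(s, s)) for s in sizes]
    return _assemble(config, noise, blocks, sizes)


def simulate_network(config: SimConfig) -> SimulatedNetwork:
    """Dispatch on ``config.noise_model``."""
    if config.noise_model == "uniform":
        return simulate_uniform(config)
    return simulate_beta(config)


def nearest_positive_definite(
    M: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Nearest positive-semidefinite correlation matrix (Higham projection).

    Alternating projection with Dykstra's correction between the PSD cone
    (eigenvalue clipping) and the unit-diagonal affine set, iterated until
    the smallest eigenvalue is >= -tol.  Raises on non-convergence.
    """
    M = np.asarray(M, dtype=float)
    if np.abs(M - M.T).max(initial=0.0) > 1e-8:
        raise ValueError("nearest_positive_definite requires a symmetric matrix")
    Y = np.array(M)
    dS = np.zeros_like(Y)
    for it in range(max_iter):
        R = Y - dS
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        if it == 0 and vals.min() >= -tol and np.allclose(np.diag(M), 1.0, atol=1e-12):
            return M  # already PSD with unit diagonal: fixed point
        X = (vecs * np.maximum(vals, 0.0)) @ vecs.T
        dS = X - R
        Y = np.array(X)
        np.fill_diagonal(Y, 1.0)
        if np.linalg.eigvalsh((Y + Y.T) / 2.0).min() >= -tol:
            return (Y + Y.T) / 2.0
    raise RuntimeError(
        f"nearest-PD projection did not converge within {max_iter} iterations"
    )


def replicate_batch(config: SimConfig, n_replicates: int) -> Iterator[SimulatedNetwork]:
    """Independent replicates with per-replicate seeds derived from config.seed."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for r in range(n_replicates):
        rep_cfg = replace(config, seed=derive_seed(config.seed, "replicate", r))
        yield simulate_network(rep_cfg)
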