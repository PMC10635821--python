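"""Synthetic expression data with planted topologies and ground truth.

The cyclic and linear generators emulate a simple binary ON/OFF gene
model: a root cell is a random {0,1}^p vector and each subsequent cell
flips the state of ``k`` uniformly chosen genes.  For the cyclic model a
forward phase of ``q`` steps is followed by a return phase that flips
genes discordant with the root until the cycle closes.  Under a
Markovian approximation the correlation between cells separated by ``m``
steps decays as ``exp(-2*m*k/p)``, which is what makes the circulant /
KMS covariance templates of :mod:`specmatch.templates` the matched
theoretical spectra.

The composite generator overlays a cyclic signal (on half the genes)
with a cluster signal (cluster-specific ON blocks on the other half) to
exercise signal enhancement and filtering with known ground truth.
Emitted matrices are row-shuffled with a recorded permutation so that
reconstruction starts from an unordered matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .preprocess import ExpressionMatrix

__all__ = [
    "SimulationParams",
    "SimulatedDataset",
    "simulate_cyclic",
    "simulate_linear",
    "simulate_composite",
]


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Parameters of the binary flip models.

    p: gene count; k: flips per step; q: forward steps (cyclic model);
    n: chain length in cells (linear model); noise_sd: optional additive
    Gaussian noise applied after binary generation; seed: the single
    source of randomness.
    """

    p: int = 500
    k: int = 5
    q: int = 50
    n: int = 100
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.p < 1 or self.k < 0 or self.q < 1 or self.n < 1:
            raise ValueError("require p >= 1, k >= 0, q >= 1, n >= 1")
        if self.k > self.p:
            raise ValueError("cannot flip more genes than exist (k > p)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclasses.dataclass(frozen=True)
class SimulatedDataset:
    """A simulated matrix plus its ground truth.

    ``matrix`` holds the shuffled cells; ``true_order[i]`` is the position
    of row ``i`` along the planted topology.  ``informative_genes`` flags
    the genes carrying the primary (cyclic) signal in composite
    simulations.  ``cluster_labels`` is present for composite data.
    """

    matrix: ExpressionMatrix
    true_order: np.ndarray
    params: SimulationParams
    informative_genes: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    def ordered_values(self) -> np.ndarray:
        """Rows sorted into the planted topological order."""
        return self.matrix.values[np.argsort(self.true_order)]

    def ordered_labels(self) -> np.ndarray | None:
        if self.cluster_labels is None:
            return None
        return self.cluster_labels[np.argsort(self.true_order)]


def _emit(values: np.ndarray, params: SimulationParams, rng: np.random.Generator,
          prefix: str, informative=None, labels=None) -> SimulatedDataset:
    tag = "counts"
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=values.shape)
        tag = "normalized"  # additive noise can go negative
    n = values.shape[0]
    perm = rng.permutation(n)  # row i of the emitted matrix sits at position perm[i]
    shuffled = values[perm]
    matrix = ExpressionMatrix(
        values=shuffled,
        cell_ids=[f"{prefix}{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(values.shape[1])],
        layer_tag=tag,
    )
    return SimulatedDataset(
        matrix=matrix,
        true_order=perm,
        params=params,
        informative_genes=informative,
        cluster_labels=None if labels is None else labels[perm],
    )


def simulate_cyclic(params: SimulationParams) -> SimulatedDataset:
    """Binary cyclic toy model.

    From a random root cell, ``q`` forward steps each flip ``k`` distinct
    uniformly chosen genes; the return phase then flips, per step, ``k``
    genes chosen among those still differing from the root (all remaining
    ones if fewer than ``k`` are left) until the cycle closes.  The final
    cell equal to the root is not emitted again, so consecutive emitted
    cells — including the wrap-around pair — differ by at most ``k``
    flips.
    """
    if params.k * params.q > params.p:
        raise ValueError(
            "infeasible cycle: k*q must not exceed p so the return path "
            "can close with distinct flips"
        )
    rng = np.random.default_rng(params.seed)
    p, k = params.p, params.k
    root = rng.integers(0, 2, size=p).astype(float)
    cells = [root.copy()]
    cell = root.copy()
    for _ in range(params.q):
        if k > 0:
            flip = rng.choice(p, size=k, replace=False)
            cell[flip] = 1.0 - cell[flip]
        cells.append(cell.copy())
    # return phase: walk back toward the root through root-discordant genes
    while not np.array_equal(cells[-1], root):
        diff = np.flatnonzero(cells[-1] != root)
        flip = rng.choice(diff, size=min(k, diff.size), replace=False)
        cell = cells[-1].copy()
        cell[flip] = 1.0 - cell[flip]
        if np.array_equal(cell, root):
            break  # cycle closed; the root is emitted only once
        cells.append(cell)
    values = np.array(cells)
    return _emit(values, params, rng, prefix="cyc")


def simulate_linear(params: SimulationParams) -> SimulatedDataset:
    """Binary linear-chain toy model: ``n`` cells, each differing from its
    predecessor by ``k`` distinct flips."""
    rng = np.random.default_rng(params.seed)
    p, k = params.p, params.k
    cell = rng.integers(0, 2, size=p).astype(float)
    cells = [cell.copy()]
    for _ in range(params.n - 1):
        if k > 0:
            flip = rng.choice(p, size=k, replace=False)
            cell[flip] = 1.0 - cell[flip]
        cells.append(cell.copy())
    return _emit(np.array(cells), params, rng, prefix="lin")


def simulate_composite(
    cyclic_params: SimulationParams,
    n_clusters: int = 4,
    cluster_strength: float = 0.5,
    seed: int | None = None,
) -> SimulatedDataset:
    """Cyclic signal overlaid with a cluster signal on disjoint gene sets.

    The first ``cyclic_params.p`` genes carry a pure cyclic toy-model
    signal; an equally sized second gene set carries cluster-specific ON
    blocks of amplitude ``cluster_strength`` (cells are assigned to
    ``n_clusters`` clusters uniformly at random, independent of cyclic
    phase).  ``informative_genes`` marks the cyclic half.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if cluster_strength < 0:
        raise ValueError("cluster_strength must be nonnegative")
    seed = cyclic_params.seed if seed is None else seed
    base = simulate_cyclic(dataclasses.replace(cyclic_params, seed=seed, noise_sd=0.0))
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31 - 1))
    n = base.n_cells
    p_cyc = cyclic_params.p

    labels = rng.integers(0, n_clusters, size=n)
    block = np.zeros((n, p_cyc))
    bounds = np.linspace(0, p_cyc, n_clusters + 1).astype(int)
    for c in range(n_clusters):
        block[labels == c, bounds[c] : bounds[c + 1]] = cluster_strength

    cyclic_ordered = base.ordered_values()
    values = np.hstack([cyclic_ordered, block])  # rows in true cyclic order here
    tag = "counts"
    if cyclic_params.noise_sd > 0:
        values = values + rng.normal(0.0, cyclic_params.noise_sd, size=values.shape)
        tag = "normalized"
    perm = rng.permutation(n)
    shuffled = values[perm]
    matrix = ExpressionMatrix(
        values=shuffled,
        cell_ids=[f"mix{i}" for i in range(n)],
        gene_ids=[f"cyc_g{j}" for j in range(p_cyc)]
        + [f"clu_g{j}" for j in range(p_cyc)],
        layer_tag=tag,
    )
    informative = np.concatenate(
        [np.ones(p_cyc, dtype=bool), np.zeros(p_cyc, dtype=bool)]
    )
    return SimulatedDataset(
        matrix=matrix,
        true_order=perm,
        params=cyclic_params,
        informative_genes=informative,
        cluster_labels=labels[perm],
    )
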