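"""Random-walk-with-restart propagation of drug-pair target signal.

Each drug combination is encoded as a seed probability vector x0 over the
network genes: the first drug's targets receive 0.5/n1 each, the second
drug's 0.5/n2 each, and shared targets the sum, so the seed always sums to 1.
The steady state of a random walk restarting at x0 with probability alpha is
the closed form

    x_T = alpha * [I - (1 - alpha) * A @ D^-1]^{-1} @ x0

where A D^-1 is the degree-normalized (column-stochastic) adjacency. Because
the propagation operator is column-stochastic, the propagated profile x_T is
non-negative and sums to 1 — probability mass is conserved.

The resolvent system is LU-factorized once per network and reused across all
combinations; a power-iteration solver is available as an independent
alternative. Profiles are stacked into a genes x combinations matrix X whose
elementwise -log transform feeds the factorization stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .dataset import CombinationDataset, CombinationRecord
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.5  # balance between local and network-wide diffusion


@dataclass(frozen=True)
class PropagationConfig:
    alpha: float = DEFAULT_ALPHA
    solver: str = "closed_form"  # or "power_iteration"
    tolerance: float = 1e-12
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"restart probability must be in (0, 1], got {self.alpha}")
        if self.solver not in ("closed_form", "power_iteration"):
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass(frozen=True)
class SeedVector:
    """Initial probability mass x0 over network genes for one combination."""

    combination: tuple[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 1 or (v < 0).any():
            raise ValueError("seed vector must be a non-negative 1-D array")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ValueError(f"seed vector must sum to 1, got {v.sum()!r}")


@dataclass
class ProfileMatrix:
    """Genes x combinations matrix X of propagated scores (columns sum to 1)."""

    matrix: np.ndarray
    genes: tuple[str, ...]
    combinations: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        n, m = self.matrix.shape
        if n != len(self.genes) or m != len(self.combinations):
            raise ValueError("matrix shape does not match gene/combination labels")
        if (self.matrix < 0).any():
            raise ValueError("propagated scores must be non-negative")
        sums = self.matrix.sum(axis=0)
        if m and not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("every propagated profile must sum to 1")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_combinations(self) -> int:
        return len(self.combinations)

    def gene_row(self, gene: str) -> np.ndarray:
        return self.matrix[self.genes.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{a}|{b}" for a, b in self.combinations]
        return pd.DataFrame(self.matrix, index=list(self.genes), columns=cols)

    def write(self, path: str | Path) -> None:
        sep = "," if str(path).lower().endswith(".csv") else "\t"
        self.to_frame().to_csv(path, sep=sep)

    @classmethod
    def read(cls, path: str | Path) -> "ProfileMatrix":
        sep = "," if str(path).lower().endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        combos = tuple(tuple(c.split("|", 1)) for c in df.columns)
        return cls(df.to_numpy(float), tuple(df.index), combos)


def build_seed_vector(
    combo: CombinationRecord, ds: CombinationDataset, network: InteractionNetwork
) -> SeedVector:
    """Seed x0: 0.5/n1 on drug A's targets, 0.5/n2 on drug B's, summed if shared."""
    values = np.zeros(network.n_genes)
    for drug_id in combo.pair:
        targets = [g for g in ds.drugs[drug_id].target_genes if g in network]
        if not targets:
            raise ValueError(
                f"drug {drug_id!r} has no in-network target; filter the dataset first"
            )
        w = 0.5 / len(targets)
        for g in targets:
            values[network.index(g)] += w
    return SeedVector(combination=combo.pair, values=values)


def normalize_adjacency(network: InteractionNetwork) -> np.ndarray:
    """Column-stochastic A @ D^-1: column j divided by degree(j)."""
    a = network.adjacency
    deg = a.sum(axis=0)
    if network.n_genes == 0 or deg.min() < 1:
        raise ValueError("every gene must have degree >= 1 for normalization")
    return a / deg[np.newaxis, :]


class _ResolventSolver:
    """LU factorization of I - (1-alpha) A D^-1, shared across seeds."""

    def __init__(self, network: InteractionNetwork, alpha: float):
        p = normalize_adjacency(network)
        system = np.eye(network.n_genes) - (1.0 - alpha) * p
        self._lu = scipy.linalg.lu_factor(system)
        self.alpha = alpha
        self._p = p

    def solve(self, seeds: np.ndarray) -> np.ndarray:
        return self.alpha * scipy.linalg.lu_solve(self._lu, seeds)

    def power_iteration(self, seed: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
        x = seed.copy()
        for _ in range(max_iter):
            x_next = (1.0 - self.alpha) * (self._p @ x) + self.alpha * seed
            if np.abs(x_next - x).sum() < tol:
                return x_next
            x = x_next
        logger.warning("power iteration did not converge to %g in %d steps", tol, max_iter)
        return x


def propagate(
    seed: SeedVector,
    network: InteractionNetwork,
    config: PropagationConfig = PropagationConfig(),
) -> np.ndarray:
    """Propagated profile x_T for one seed vector."""
    solver = _ResolventSolver(network, config.alpha)
    if config.solver == "power_iteration":
        x = solver.power_iteration(seed.values, config.tolerance, config.max_iter)
    else:
        x = solver.solve(seed.values)
    return np.clip(x, 0.0, None)


def propagate_all(
    ds: CombinationDataset,
    network: InteractionNetwork,
    config: PropagationConfig = PropagationConfig(),
) -> ProfileMatrix:
    """Propagate every combination, reusing one factorization of the resolvent."""
    solver = _ResolventSolver(network, config.alpha)
    seeds = np.column_stack(
        [build_seed_vector(c, ds, network).values for c in ds.combinations]
    )
    if config.solver == "power_iteration":
        x = np.column_stack(
            [
                solver.power_iteration(seeds[:, j], config.tolerance, config.max_iter)
                for j in range(seeds.shape[1])
            ]
        )
    else:
        x = solver.solve(seeds)
    x = np.clip(x, 0.0, None)
    x /= x.sum(axis=0, keepdims=True)  # remove roundoff drift; mass is conserved
    return ProfileMatrix(
        matrix=x, genes=network.genes, combinations=tuple(c.pair for c in ds.combinations)
    )


def neglog_transform(x: ProfileMatrix | np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Elementwise -log(max(X, floor)); maps [0, 1] scores to non-negative values.

    The transform reverses ordering: the highest propagated scores (direct
    drug targets) become the smallest transformed values, which is why the
    most important genes of a metagene are those with the *lowest* weights.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    m = x.matrix if isinstance(x, ProfileMatrix) else np.asarray(x, float)
    if (m < 0).any():
        raise ValueError("propagated scores must be non-negative")
    n_floored = int((m < floor).sum())
    if n_floored:
        logger.info("floored %d entries below %g before -log", n_floored, floor)
    return -np.log(np.maximum(m, floor))
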