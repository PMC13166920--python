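"""Graph-regularized non-negative matrix factorization (GNMF).

Factorizes the (-log-transformed) propagated profile matrix X' (N genes x M
combinations) into non-negative W (N x K) and H (K x M) so that X' ~ W @ H.
Each column of W is a metagene — a weighted gene group acting as a
pathway-level feature; H gives each drug combination's loading on each
metagene. The factorization is regularized by the gene-network Laplacian
L = D - A so that genes adjacent in the cancer network receive similar
metagene weights:

    J(W, H) = ||X' - W H||_F^2 + lam * tr(W^T L W),      0 <= lam <= 1

minimized by multiplicative updates

    W <- W * (X' H^T + lam * A W) / (W H H^T + lam * D W)
    H <- H * (W^T X') / (W^T W H)

which preserve non-negativity and weakly decrease J at every step. An
alternative convex-mixture objective (1 - lam) ||.||^2 + lam tr(.) is
available behind a config flag.

Model order K is chosen by the elbow (knee) of the reconstruction-error
curve over a K scan, using the Kneedle criterion: after min-max normalizing
the curve, the selected K maximizes the vertical distance between the curve
and the straight line joining its endpoints. The error tracked for the scan
is the pure reconstruction term ||X' - W H||_F, without the penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import InteractionNetwork

logger = logging.getLogger(__name__)

_EPS = 1e-10  # denominator stabilizer in the multiplicative updates


@dataclass(frozen=True)
class FactorizationConfig:
    """Settings for one GNMF fit.

    lam weighs the graph-smoothness penalty; 0 recovers plain NMF. With
    ``convex_mix`` the objective is (1-lam)*reconstruction + lam*penalty
    instead of reconstruction + lam*penalty.
    """

    k: int = 26
    lam: float = 0.9
    max_iter: int = 1000
    rel_tol: float = 1e-6
    n_restarts: int = 5
    rng_seed: int = 42
    convex_mix: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")


@dataclass
class FactorizationResult:
    W: np.ndarray
    H: np.ndarray
    objective_trace: np.ndarray
    reconstruction_error: float
    config: FactorizationConfig
    genes: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return self.W.shape[1]


@dataclass
class KneeScan:
    k_values: tuple[int, ...]
    errors: tuple[float, ...]
    selected_k: int | None = None


def _init_factors(
    rng: np.random.Generator, n: int, m: int, k: int, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    return rng.uniform(0.0, 1.0, (n, k)) * scale, rng.uniform(0.0, 1.0, (k, m)) * scale


def _objective(
    xp: np.ndarray, w: np.ndarray, h: np.ndarray,
    lap: np.ndarray, lam: float, convex_mix: bool,
) -> float:
    recon = float(np.linalg.norm(xp - w @ h) ** 2)
    penalty = float(np.trace(w.T @ lap @ w))
    if convex_mix:
        return (1.0 - lam) * recon + lam * penalty
    return recon + lam * penalty


def _fit_single(
    xp: np.ndarray,
    adj: np.ndarray,
    deg: np.ndarray,
    config: FactorizationConfig,
    seed: np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n, m = xp.shape
    k, lam = config.k, config.lam
    rng = np.random.default_rng(seed)
    w, h = _init_factors(rng, n, m, k, scale=float(xp.mean()) / k)
    lap = np.diag(deg) - adj
    rw = 1.0 - lam if config.convex_mix else 1.0  # weight on the reconstruction term
    trace = [_objective(xp, w, h, lap, lam, config.convex_mix)]
    for _ in range(config.max_iter):
        num_w = rw * (xp @ h.T) + lam * (adj @ w)
        den_w = rw * (w @ (h @ h.T)) + lam * (deg[:, None] * w)
        w *= num_w / (den_w + _EPS)
        num_h = w.T @ xp
        den_h = (w.T @ w) @ h
        h *= num_h / (den_h + _EPS)
        obj = _objective(xp, w, h, lap, lam, config.convex_mix)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and abs(prev - obj) / prev < config.rel_tol:
            break
    return w, h, trace


def gnmf_factorize(
    xp: np.ndarray,
    network: InteractionNetwork,
    config: FactorizationConfig = FactorizationConfig(),
) -> FactorizationResult:
    """Best-of-restarts GNMF fit of a non-negative matrix.

    Rows of ``xp`` must align with ``network.genes``. Runs
    ``config.n_restarts`` random initializations with seeds derived
    deterministically from ``config.rng_seed`` and returns the solution with
    the lowest final objective.
    """
    xp = np.asarray(xp, float)
    if (xp < 0).any():
        raise ValueError("GNMF input must be non-negative")
    if xp.shape[0] != network.n_genes:
        raise ValueError(
            f"row count {xp.shape[0]} does not match network size {network.n_genes}"
        )
    if config.k > min(xp.shape):
        raise ValueError(f"K={config.k} exceeds min(N, M)={min(xp.shape)}")
    adj = network.adjacency
    deg = network.degree
    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    # (rng_seed, K)-keyed seeds: a K scan and a direct fit at the same K see
    # identical restarts
    seeds = np.random.SeedSequence([config.rng_seed, config.k]).spawn(config.n_restarts)
    for seed in seeds:
        w, h, trace = _fit_single(xp, adj, deg, config, seed)
        if not np.isfinite(trace[-1]):
            raise FloatingPointError("GNMF objective became non-finite")
        if best is None or trace[-1] < best[2][-1]:
            best = (w, h, trace)
    assert best is not None
    w, h, trace = best
    return FactorizationResult(
        W=w,
        H=h,
        objective_trace=np.array(trace),
        reconstruction_error=float(np.linalg.norm(xp - w @ h)),
        config=config,
        genes=network.genes,
    )


def scan_k(
    xp: np.ndarray,
    network: InteractionNetwork,
    k_range: Sequence[int],
    config: FactorizationConfig = FactorizationConfig(),
) -> KneeScan:
    """Best-of-restarts reconstruction error for each K in ``k_range``.

    Restarts are independent per (K, restart), with seeds derived from
    ``config.rng_seed`` so the scan is reproducible. The recorded error is
    the pure reconstruction term ||X' - WH||_F of the best restart.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    errors = []
    for k in ks:
        cfg = FactorizationConfig(
            k=k, lam=config.lam, max_iter=config.max_iter, rel_tol=config.rel_tol,
            n_restarts=config.n_restarts, rng_seed=config.rng_seed,
            convex_mix=config.convex_mix,
        )
        res = gnmf_factorize(xp, network, cfg)
        errors.append(res.reconstruction_error)
        logger.debug("K=%d reconstruction error %.6g", k, errors[-1])
    return KneeScan(k_values=tuple(ks), errors=tuple(errors))


def find_elbow(scan: KneeScan, min_gap: float = 1e-8) -> int:
    """Kneedle elbow of a decreasing convex error curve.

    Min-max normalizes (K, error), then returns the K maximizing the
    vertical distance between the chord joining the curve's endpoints and
    the curve itself. A flat or straight-line curve has no elbow and raises.
    """
    ks = np.asarray(scan.k_values, float)
    errs = np.asarray(scan.errors, float)
    if ks.size < 3:
        raise ValueError("need at least 3 scan points to locate an elbow")
    if errs.max() == errs.min():
        raise ValueError("error curve is constant; widen the K range")
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y = (errs - errs.min()) / (errs.max() - errs.min())
    chord = y[0] + (y[-1] - y[0]) * x
    dist = chord - y  # >= 0 where the curve sags below the chord
    if dist.max() <= min_gap:
        raise ValueError("error curve has no elbow (near-linear); widen the K range")
    selected = int(ks[int(np.argmax(dist))])
    scan.selected_k = selected
    return selected


def normalize_factors(
    w: np.ndarray, h: np.ndarray, norm: str = "l2"
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve NMF scale indeterminacy: unit-norm W columns, compensated H.

    Leaves the product W @ H (hence the reconstruction term) unchanged while
    making H rows comparable across metagenes, which the clustering and
    dominance analyses require.
    """
    w = np.asarray(w, float)
    h = np.asarray(h, float)
    scale = np.linalg.norm(w, axis=0) if norm == "l2" else w.sum(axis=0)
    if (scale == 0).any():
        raise ValueError("cannot normalize a zero metagene column")
    return w / scale, h * scale[:, None]


def top_genes(
    result: FactorizationResult, metagene_index: int, n: int = 200
) -> list[str]:
    """The n genes contributing most to one metagene.

    Because the factorized matrix is -log(X), the strongest contributors are
    the genes with the *smallest* weights in the metagene's W column; the
    list is returned in ascending weight order, ties broken lexicographically.
    """
    if not 0 <= metagene_index < result.k:
        raise IndexError(f"metagene index {metagene_index} out of range 0..{result.k - 1}")
    if not result.genes:
        raise ValueError("factorization result carries no gene labels")
    if n > len(result.genes):
        raise ValueError(f"n={n} exceeds the number of genes {len(result.genes)}")
    col = result.W[:, metagene_index]
    order = sorted(range(len(col)), key=lambda i: (col[i], result.genes[i]))
    return [result.genes[i] for i in order[:n]]
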