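"""End-to-end orchestration of the propagation/factorization/analysis stages.

Ties the modules together in the order the method runs: network filtering,
dataset filtering, RWR propagation, -log transform, (optionally K-scan +)
GNMF, Ward clustering of H, enriched-cluster selection and the metagene
dominance test. Each stage remains individually callable; this module only
sequences them and gathers the intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import (
    AnalysisConfig,
    ClusterCandidate,
    cluster_report,
    dedup_lineages,
    enumerate_enriched_clusters,
    hierarchical_cluster,
    metagene_dominance_test,
)
from .dataset import CombinationDataset, DEFAULT_INHIBITORY_ACTIONS, filter_dataset
from .gnmf import (
    FactorizationConfig,
    FactorizationResult,
    KneeScan,
    find_elbow,
    gnmf_factorize,
    normalize_factors,
    scan_k,
    top_genes,
)
from .network import GeneSet, InteractionNetwork, MutationTable, induce_subnetwork, merge_gene_sets, remove_lof_genes
from .propagation import PropagationConfig, ProfileMatrix, neglog_transform, propagate_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    network: InteractionNetwork
    dataset: CombinationDataset
    profiles: ProfileMatrix
    transformed: np.ndarray
    factorization: FactorizationResult
    linkage: np.ndarray
    candidates: list[ClusterCandidate]
    final_clusters: list[ClusterCandidate]
    dominance: pd.DataFrame
    knee_scan: KneeScan | None = None

    @property
    def report(self) -> pd.DataFrame:
        return cluster_report(self.final_clusters, self.dataset)

    @property
    def dominant_metagenes(self) -> list[int]:
        d = self.dominance
        return d.loc[d["dominant"], "metagene"].tolist()


def build_analysis_network(
    network: InteractionNetwork,
    gene_sets: Sequence[GeneSet] | None = None,
    mutations: MutationTable | None = None,
) -> InteractionNetwork:
    """Apply the cancer-gene-set and loss-of-function filters, if given."""
    if gene_sets:
        network = induce_subnetwork(network, merge_gene_sets(list(gene_sets)))
    if mutations is not None:
        network = remove_lof_genes(network, mutations)
    network.validate()
    return network


def run_pipeline(
    network: InteractionNetwork,
    ds: CombinationDataset,
    gene_sets: Sequence[GeneSet] | None = None,
    mutations: MutationTable | None = None,
    inhibitory_actions=DEFAULT_INHIBITORY_ACTIONS,
    propagation_config: PropagationConfig = PropagationConfig(),
    factorization_config: FactorizationConfig = FactorizationConfig(),
    analysis_config: AnalysisConfig = AnalysisConfig(),
    k_scan_range: Sequence[int] | None = None,
    scan_config: FactorizationConfig | None = None,
    neglog_floor: float = 1e-12,
) -> PipelineResult:
    """Run the full analysis; if ``k_scan_range`` is given, K is chosen by elbow.

    ``scan_config`` optionally uses cheaper optimization settings for the K
    scan than for the final fit.
    """
    network = build_analysis_network(network, gene_sets, mutations)
    ds = filter_dataset(ds, network, inhibitory_actions)
    profiles = propagate_all(ds, network, propagation_config)
    transformed = neglog_transform(profiles, floor=neglog_floor)

    knee = None
    fcfg = factorization_config
    if k_scan_range is not None:
        knee = scan_k(transformed, network, k_scan_range, scan_config or fcfg)
        selected = find_elbow(knee)
        logger.info("elbow-selected K = %d", selected)
        fcfg = FactorizationConfig(
            k=selected, lam=fcfg.lam, max_iter=fcfg.max_iter, rel_tol=fcfg.rel_tol,
            n_restarts=fcfg.n_restarts, rng_seed=fcfg.rng_seed, convex_mix=fcfg.convex_mix,
        )
    fact = gnmf_factorize(transformed, network, fcfg)
    # resolve scale indeterminacy so H rows are comparable across metagenes
    w_n, h_n = normalize_factors(fact.W, fact.H)
    fact.W, fact.H = w_n, h_n

    linkage = hierarchical_cluster(fact.H)
    candidates = enumerate_enriched_clusters(linkage, ds, analysis_config)
    final = dedup_lineages(candidates)
    if final:
        dominance = metagene_dominance_test(fact.H, final, analysis_config)
    else:
        dominance = pd.DataFrame(columns=["metagene", "max_adj_p", "dominant"])
    return PipelineResult(
        network=network, dataset=ds, profiles=profiles, transformed=transformed,
        factorization=fact, linkage=linkage, candidates=candidates,
        final_clusters=final, dominance=dominance, knee_scan=knee,
    )


# ---------------------------------------------------------------------------
# Synthetic recovery experiment
# ---------------------------------------------------------------------------

#: Factorization settings for synthetic recovery runs. The convex-mixture
#: objective is used so that lam = 0.9 exerts real smoothing pressure at the
#: synthetic problem scale, and 12 restarts are run because split-basis local
#: minima (two metagenes sharing one module) otherwise occur occasionally.
RECOVERY_FACTORIZATION = dict(lam=0.9, convex_mix=True, n_restarts=12,
                              max_iter=1000, rel_tol=1e-6)
RECOVERY_SCAN = dict(n_restarts=2, max_iter=300, rel_tol=1e-5)
RECOVERY_K_RANGE = range(2, 13)


@dataclass
class RecoveryOutcome:
    """Planted-structure recovery measurements for one synthetic run."""

    selected_k: int
    planted_metagene: int
    planted_overlap: float          # top-|module| gene overlap with the module
    planted_dominant: bool          # planted metagene passes the dominance test
    any_dominant: bool              # any metagene declared dominant
    n_final_clusters: int
    best_cluster_purity: float      # max fraction of planted pairs in a final cluster
    screen_precision: float | None  # planted-module precision of the HSA gene screen
    result: PipelineResult


def identify_planted_metagene(
    fact: FactorizationResult, module_genes: frozenset[str]
) -> tuple[int, float]:
    """Metagene whose top-|module| gene list best overlaps the planted module."""
    present = module_genes & set(fact.genes)
    if not present:
        raise ValueError("planted module has no genes in the analysis network")
    best_k, best_ov = 0, -1.0
    for k in range(fact.k):
        top = set(top_genes(fact, k, n=len(present)))
        ov = len(top & present) / len(present)
        if ov > best_ov:
            best_k, best_ov = k, ov
    return best_k, best_ov


def run_synthetic_recovery(
    config=None,
    gnmf_seed: int = 42,
    analysis_config: AnalysisConfig = AnalysisConfig(),
    compute_screen_precision: bool = False,
) -> RecoveryOutcome:
    """End-to-end pipeline on one synthetic draw, scored against ground truth.

    Runs the full analysis — LoF filtering, dataset filtering, propagation,
    -log transform, elbow-selected GNMF, clustering, enrichment selection and
    the dominance test — and measures whether the planted module's metagene
    is recovered and dominant, and how pure the recovered clusters are.
    """
    from .analysis import quartile_gene_screen
    from .synthetic import SyntheticConfig, generate_bundle

    if config is None:
        config = SyntheticConfig()
    bundle = generate_bundle(config)
    fcfg = FactorizationConfig(k=2, rng_seed=gnmf_seed, **RECOVERY_FACTORIZATION)
    scan_cfg = FactorizationConfig(
        k=2, lam=fcfg.lam, convex_mix=fcfg.convex_mix, rng_seed=gnmf_seed,
        **RECOVERY_SCAN,
    )
    result = run_pipeline(
        bundle.network, bundle.dataset, mutations=bundle.mutations,
        factorization_config=fcfg, analysis_config=analysis_config,
        k_scan_range=RECOVERY_K_RANGE, scan_config=scan_cfg,
    )
    module = bundle.truth.module_genes(bundle.truth.planted_module)
    kstar, overlap = identify_planted_metagene(result.factorization, module)
    dominant = result.dominant_metagenes
    mask = bundle.truth.planted_mask(result.dataset)
    purities = [
        float(np.mean([mask[i] for i in c.members])) for c in result.final_clusters
    ]
    precision = None
    if compute_screen_precision:
        screen = quartile_gene_screen(
            result.profiles, result.dataset, "HSA", analysis_config
        )
        # planted-module genes are the positively associated markers; genes
        # flagged with the opposite sign are mass-conservation counterparts
        # (high planted scores drain probability mass from other modules)
        lo = np.flatnonzero(screen.quarters == 1)
        hi = np.flatnonzero(screen.quarters == 4)
        gidx = {g: i for i, g in enumerate(result.profiles.genes)}
        positive = [
            g for g in screen.significant_genes
            if np.median(result.profiles.matrix[gidx[g], hi])
            > np.median(result.profiles.matrix[gidx[g], lo])
        ]
        if positive:
            precision = float(np.mean([g in module for g in positive]))
    return RecoveryOutcome(
        selected_k=result.factorization.k,
        planted_metagene=kstar,
        planted_overlap=overlap,
        planted_dominant=kstar in dominant,
        any_dominant=bool(dominant),
        n_final_clusters=len(result.final_clusters),
        best_cluster_purity=max(purities, default=0.0),
        screen_precision=precision,
        result=result,
    )
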