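"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates the four input tables the analysis consumes — an interaction
network, drugs with small inhibitory target sets, drug pairs with four
correlated synergy scores, and a mutation table — with a known ground truth
so recovery is measurable end to end:

* the network is a stochastic block model, so metagenes have a planted
  modular counterpart;
* each drug's targets concentrate in one "home" module;
* high synergy is planted on pairs in which BOTH drugs target a designated
  module: each of the four scores is baseline Normal(0, noise_sd) plus the
  effect delta scaled by a fixed per-metric factor, mimicking the partial
  agreement among HSA/ZIP/Bliss/Loewe without modelling dose-response
  surfaces;
* loss-of-function labels avoid the planted module, so the signal survives
  network filtering.

All draws are fully determined by ``rng_seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .dataset import (
    SYNERGY_METRICS,
    CombinationDataset,
    CombinationRecord,
    DrugRecord,
    write_dataset,
)
from .network import (
    GAIN_OF_FUNCTION,
    LOSS_OF_FUNCTION,
    UNKNOWN,
    InteractionNetwork,
    MutationTable,
    write_edge_list,
)

logger = logging.getLogger(__name__)

#: Per-metric scaling of the planted synergy effect, mimicking the observed
#: partial agreement among the four scores.
METRIC_EFFECT_SCALE = {"HSA": 1.0, "ZIP": 0.8, "Bliss": 0.9, "Loewe": 0.6}

#: Probability that a drug target falls inside the drug's home module.
HOME_TARGET_PROB = 0.8

#: Sampling weight of the planted module when assigning drug home modules,
#: relative to weight 1 for every other module. Keeps enough planted-module
#: drugs for planted pairs to populate a cluster-sized group.
PLANTED_MODULE_WEIGHT = 2.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 300
    n_modules: int = 6
    p_in: float = 0.25
    p_out: float = 0.01
    n_drugs: int = 30
    targets_per_drug: tuple[int, int] = (1, 4)
    n_combos: int = 120
    synergy_module: int = 0
    effect_size: float = 8.0
    noise_sd: float = 3.0
    lof_fraction: float = 0.05
    planted_fraction: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_in < 1 and 0 < self.p_out < 1):
            raise ValueError("edge probabilities must be in (0, 1)")
        if self.n_combos > self.n_drugs * (self.n_drugs - 1) // 2:
            raise ValueError("n_combos exceeds the number of distinct drug pairs")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.synergy_module < self.n_modules:
            raise ValueError("synergy_module out of range")
        if self.lof_fraction >= 0.5:
            raise ValueError("lof_fraction must be < 0.5")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic draw."""

    module_of: Mapping[str, int]      # gene -> module label
    planted_module: int
    planted: Mapping[tuple[str, str], bool]  # canonical pair -> synergy-driven?

    def planted_mask(self, ds: CombinationDataset) -> np.ndarray:
        return np.array([self.planted.get(rec.pair, False) for rec in ds.combinations])

    def module_genes(self, module: int) -> frozenset[str]:
        return frozenset(g for g, m in self.module_of.items() if m == module)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"  # zero-padded so lexicographic order == numeric order


def generate_network(config: SyntheticConfig) -> tuple[InteractionNetwork, dict[str, int]]:
    """Stochastic-block-model network; only the largest component is kept."""
    base = config.n_genes // config.n_modules
    sizes = [base + (1 if i < config.n_genes % config.n_modules else 0)
             for i in range(config.n_modules)]
    probs = [
        [config.p_in if i == j else config.p_out for j in range(config.n_modules)]
        for i in range(config.n_modules)
    ]
    g = nx.stochastic_block_model(
        sizes, probs, seed=int(np.random.SeedSequence([config.rng_seed, 0]).generate_state(1)[0])
    )
    if g.number_of_edges() == 0:
        raise ValueError("degenerate synthetic graph: no edges; increase p_in")
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    keep = components[0]
    module_of_node = {n: g.nodes[n]["block"] for n in g.nodes}
    edges = [
        (_gene_name(a), _gene_name(b)) for a, b in g.edges if a in keep and b in keep
    ]
    network = InteractionNetwork.from_edges(edges)
    labels = {g_: module_of_node[int(g_[1:])] for g_ in network.genes}
    logger.info(
        "synthetic network: %d genes (%d in largest component), %d edges",
        config.n_genes, network.n_genes, network.n_edges,
    )
    return network, labels


def generate_drugs_and_combos(
    network: InteractionNetwork,
    labels: Mapping[str, int],
    config: SyntheticConfig,
) -> tuple[CombinationDataset, SyntheticTruth]:
    """Drugs with module-concentrated targets plus planted-synergy pairs."""
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    module_genes: dict[int, list[str]] = {m: [] for m in range(config.n_modules)}
    for gene in network.genes:
        module_genes[labels[gene]].append(gene)
    nonempty = [m for m in range(config.n_modules) if module_genes[m]]
    weights = np.array(
        [PLANTED_MODULE_WEIGHT if m == config.synergy_module else 1.0 for m in nonempty]
    )
    weights /= weights.sum()

    drugs: dict[str, DrugRecord] = {}
    home_of: dict[str, int] = {}
    lo, hi = config.targets_per_drug
    for i in range(config.n_drugs):
        drug_id = f"D{i:03d}"
        home = int(rng.choice(nonempty, p=weights))
        home_of[drug_id] = home
        n_targets = int(rng.integers(lo, hi + 1))
        # first target guaranteed in the home module so a drug genuinely
        # engages the module it is assigned to; the rest mostly follow
        targets: set[str] = {module_genes[home][int(rng.integers(len(module_genes[home])))]}
        while len(targets) < n_targets:
            if rng.random() < HOME_TARGET_PROB or len(nonempty) == 1:
                pool = module_genes[home]
            else:
                other = int(rng.choice([m for m in nonempty if m != home]))
                pool = module_genes[other]
            targets.add(pool[int(rng.integers(len(pool)))])
        drugs[drug_id] = DrugRecord(
            drug_id, drug_id, tuple((g, "inhibitor") for g in sorted(targets))
        )

    # planted pairs co-target the designated module: both drugs live there
    capable = [d for d in drugs if home_of[d] == config.synergy_module]
    all_ids = sorted(drugs)
    all_pairs = [
        (all_ids[i], all_ids[j])
        for i in range(len(all_ids))
        for j in range(i + 1, len(all_ids))
    ]
    capable_set = set(capable)
    planted_pool = [p for p in all_pairs if p[0] in capable_set and p[1] in capable_set]
    background_pool = [p for p in all_pairs if p not in set(planted_pool)]
    n_planted = min(round(config.planted_fraction * config.n_combos), len(planted_pool))
    n_background = config.n_combos - n_planted
    if n_background > len(background_pool):
        raise ValueError("n_combos infeasible for the drawn drug set")
    chosen_planted = [
        planted_pool[i]
        for i in rng.choice(len(planted_pool), size=n_planted, replace=False)
    ]
    chosen_background = [
        background_pool[i]
        for i in rng.choice(len(background_pool), size=n_background, replace=False)
    ]

    records = []
    planted_flags: dict[tuple[str, str], bool] = {}
    for pair, is_planted in [(p, True) for p in chosen_planted] + [
        (p, False) for p in chosen_background
    ]:
        scores = {
            met: float(
                rng.normal(0.0, config.noise_sd)
                + (config.effect_size * METRIC_EFFECT_SCALE[met] if is_planted else 0.0)
            )
            for met in SYNERGY_METRICS
        }
        records.append(CombinationRecord(pair[0], pair[1], scores))
        planted_flags[pair] = is_planted
    records.sort(key=lambda r: r.pair)
    ds = CombinationDataset(drugs=drugs, combinations=tuple(records))
    truth = SyntheticTruth(
        module_of=dict(labels),
        planted_module=config.synergy_module,
        planted=planted_flags,
    )
    logger.info(
        "synthetic dataset: %d drugs, %d combinations (%d planted)",
        len(drugs), len(records), n_planted,
    )
    return ds, truth


def generate_mutations(
    network: InteractionNetwork,
    config: SyntheticConfig,
    labels: Mapping[str, int] | None = None,
    truth: SyntheticTruth | None = None,
) -> MutationTable:
    """LoF labels on a fraction of non-planted-module genes, plus GoF/unknown.

    The planted module is protected from loss-of-function removal so the
    planted signal survives network filtering.
    """
    module_of = truth.module_of if truth is not None else (labels or {})
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    eligible = sorted(
        g for g in network.genes if module_of.get(g) != config.synergy_module
    )
    n_lof = round(config.lof_fraction * len(eligible))
    order = list(rng.permutation(len(eligible)))
    lof = [eligible[i] for i in order[:n_lof]]
    n_other = min(n_lof, len(eligible) - n_lof)
    gof = [eligible[i] for i in order[n_lof : n_lof + n_other // 2]]
    unk = [eligible[i] for i in order[n_lof + n_other // 2 : n_lof + n_other]]
    records = (
        [(g, LOSS_OF_FUNCTION) for g in lof]
        + [(g, GAIN_OF_FUNCTION) for g in gof]
        + [(g, UNKNOWN) for g in unk]
    )
    return MutationTable.from_records(records)


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    network: InteractionNetwork
    labels: dict[str, int]
    dataset: CombinationDataset
    truth: SyntheticTruth
    mutations: MutationTable


def generate_bundle(config: SyntheticConfig = SyntheticConfig()) -> SyntheticBundle:
    """All four synthetic inputs plus ground truth, in one call."""
    network, labels = generate_network(config)
    ds, truth = generate_drugs_and_combos(network, labels, config)
    mutations = generate_mutations(network, config, truth=truth)
    return SyntheticBundle(config, network, labels, ds, truth, mutations)


def write_fixture(directory: str | Path, config: SyntheticConfig = SyntheticConfig()) -> SyntheticBundle:
    """Emit the full input bundle in the formats the pipeline CLIs consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)
    write_edge_list(bundle.network, directory / "network_edges.csv")
    write_dataset(
        bundle.dataset, directory / "combinations.csv", directory / "drugs.csv"
    )
    (directory / "gene_set_all.txt").write_text(
        "\n".join(bundle.network.genes) + "\n"
    )
    with open(directory / "mutations.csv", "w") as fh:
        fh.write("gene,category\n")
        for gene, cat in bundle.mutations.records:
            fh.write(f"{gene},{cat}\n")
    manifest = {
        "config": asdict(bundle.config),
        "planted_module": bundle.truth.planted_module,
        "module_of": bundle.truth.module_of,
        "planted_pairs": sorted(
            [list(p) for p, f in bundle.truth.planted.items() if f]
        ),
    }
    (directory / "truth_manifest.json").write_text(json.dumps(manifest, indent=1))
    return bundle
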