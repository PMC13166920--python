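import numpy as np
import pandas as pd
import pytest

from metasyn import (
    CombinationDataset,
    CombinationRecord,
    DrugRecord,
    InteractionNetwork,
)


@pytest.fixture
def triangle() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3() -> InteractionNetwork:
    """Path graph A - B - C."""
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def random_network() -> InteractionNetwork:
    """Connected Erdos-Renyi-style fixture graph on 30 nodes."""
    rng = np.random.default_rng(11)
    n = 30
    edges = [(f"N{i:02d}", f"N{(i + 1) % n:02d}") for i in range(n)]  # cycle: connected
    for _ in range(60):
        i, j = rng.choice(n, size=2, replace=False)
        edges.append((f"N{i:02d}", f"N{j:02d}"))
    return InteractionNetwork.from_edges(edges)


def make_dataset(pairs_scores, drug_targets) -> CombinationDataset:
    """Assemble a small in-memory dataset.

    pairs_scores: list of ((a, b), {metric: score} or scalar applied to all).
    drug_targets: {drug_id: [gene, ...]} (all actions 'inhibitor').
    """
    drugs = {
        d: DrugRecord(d, d, tuple((g, "inhibitor") for g in sorted(genes)))
        for d, genes in drug_targets.items()
    }
    records = []
    for (a, b), scores in pairs_scores:
        if not isinstance(scores, dict):
            scores = {m: float(scores) for m in ("HSA", "ZIP", "Bliss", "Loewe")}
        a, b = (a, b) if a < b else (b, a)
        records.append(CombinationRecord(a, b, scores))
    records.sort(key=lambda r: r.pair)
    return CombinationDataset(drugs=drugs, combinations=tuple(records))


@pytest.fixture
def small_dataset(triangle) -> CombinationDataset:
    return make_dataset(
        [(("D1", "D2"), 1.0), (("D1", "D3"), 2.0), (("D2", "D3"), 3.0), (("D1", "D4"), 4.0)],
        {"D1": ["A"], "D2": ["B"], "D3": ["A", "C"], "D4": ["B", "C"]},
    )
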