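"""Drug-combination dataset assembly and filtering.

A combination dataset couples unordered drug pairs carrying four synergy
scores (HSA, ZIP, Bliss, Loewe; positive = synergistic, negative =
antagonistic) with per-drug inhibitory target sets. Only inhibitory
drug-target actions are retained, and targets are restricted to genes present
in the analysis network; a drug left with no usable target is dropped
together with every combination containing it. The per-drug in-network
target count defines the seed weighting used by propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import InteractionNetwork, normalize_symbol

logger = logging.getLogger(__name__)

SYNERGY_METRICS = ("HSA", "ZIP", "Bliss", "Loewe")

#: Drug-target action labels treated as inhibitory by default. The source
#: vocabularies are free-text, so this set is configurable at the call site.
DEFAULT_INHIBITORY_ACTIONS = frozenset(
    {"inhibitor", "antagonist", "blocker", "negative modulator", "suppressor"}
)


@dataclass(frozen=True)
class DrugRecord:
    """One drug with its (gene symbol, action label) targets."""

    drug_id: str
    name: str
    targets: tuple[tuple[str, str], ...]

    @property
    def target_genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.targets)


@dataclass(frozen=True)
class CombinationRecord:
    """An unordered drug pair with its four synergy scores.

    The pair is canonicalized so ``drug_a < drug_b``.
    """

    drug_a: str
    drug_b: str
    synergy: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.drug_a >= self.drug_b:
            raise ValueError("pair must be canonicalized with drug_a < drug_b")
        missing = set(SYNERGY_METRICS) - set(self.synergy)
        if missing:
            raise ValueError(f"missing synergy scores: {sorted(missing)}")
        for m in SYNERGY_METRICS:
            if not np.isfinite(self.synergy[m]):
                raise ValueError(f"non-finite {m} score for pair ({self.drug_a}, {self.drug_b})")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


@dataclass(frozen=True)
class CombinationDataset:
    drugs: Mapping[str, DrugRecord]
    combinations: tuple[CombinationRecord, ...]

    def __post_init__(self) -> None:
        for rec in self.combinations:
            for d in rec.pair:
                if d not in self.drugs:
                    raise ValueError(f"combination references unknown drug {d!r}")

    @property
    def n_combinations(self) -> int:
        return len(self.combinations)

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.drugs))

    def scores(self, metric: str) -> np.ndarray:
        """Synergy scores for one metric, in combination order."""
        _check_metric(metric)
        return np.array([rec.synergy[metric] for rec in self.combinations])

    def combinations_with(self, drug_id: str) -> tuple[int, ...]:
        """Indices of combinations containing the given drug."""
        return tuple(i for i, r in enumerate(self.combinations) if drug_id in r.pair)

    def target_count(self, drug_id: str) -> int:
        return len(self.drugs[drug_id].target_genes)


def _check_metric(metric: str) -> None:
    if metric not in SYNERGY_METRICS:
        raise ValueError(f"unknown synergy metric {metric!r}; expected one of {SYNERGY_METRICS}")


def load_dataset(
    combo_table: pd.DataFrame, drug_table: pd.DataFrame
) -> CombinationDataset:
    """Assemble a dataset from a combination table and a drug-target table.

    Pairs are canonicalized to unordered form; rows describing the same
    unordered pair are collapsed by averaging each synergy score (replicate
    measurements). Any combination referencing a drug absent from the drug
    table is a hard error.
    """
    combo_cols = {c.lower(): c for c in combo_table.columns}
    for needed in ("drug_a", "drug_b", "hsa", "zip", "bliss", "loewe"):
        if needed not in combo_cols:
            raise ValueError(f"combination table missing column {needed!r}")
    drug_cols = {c.lower(): c for c in drug_table.columns}
    for needed in ("drug_id", "target_gene", "action"):
        if needed not in drug_cols:
            raise ValueError(f"drug table missing column {needed!r}")

    drugs: dict[str, DrugRecord] = {}
    name_col = drug_cols.get("name")
    for drug_id, grp in drug_table.groupby(drug_cols["drug_id"], sort=True):
        drug_id = str(drug_id).strip()
        targets: dict[str, str] = {}
        for _, row in grp.iterrows():
            gene = normalize_symbol(row[drug_cols["target_gene"]])
            action = str(row[drug_cols["action"]]).strip().lower()
            targets.setdefault(gene, action)
        name = str(grp.iloc[0][name_col]) if name_col else drug_id
        drugs[drug_id] = DrugRecord(drug_id, name, tuple(sorted(targets.items())))

    pooled: dict[tuple[str, str], list[dict[str, float]]] = {}
    for _, row in combo_table.iterrows():
        a, b = str(row[combo_cols["drug_a"]]).strip(), str(row[combo_cols["drug_b"]]).strip()
        if a == b:
            raise ValueError(f"self-combination {a!r} is not allowed")
        pair = (a, b) if a < b else (b, a)
        for d in pair:
            if d not in drugs:
                raise ValueError(f"combination ({a}, {b}) references unknown drug {d!r}")
        scores = {}
        for metric, col_key in zip(SYNERGY_METRICS, ("hsa", "zip", "bliss", "loewe")):
            val = pd.to_numeric(row[combo_cols[col_key]], errors="coerce")
            if pd.isna(val):
                raise ValueError(f"non-numeric {metric} score for pair ({a}, {b})")
            scores[metric] = float(val)
        pooled.setdefault(pair, []).append(scores)

    n_dup = sum(len(v) - 1 for v in pooled.values())
    if n_dup:
        logger.info("collapsed %d duplicate combination rows by score averaging", n_dup)
    combos = tuple(
        CombinationRecord(
            a, b,
            {m: float(np.mean([s[m] for s in reps])) for m in SYNERGY_METRICS},
        )
        for (a, b), reps in sorted(pooled.items())
    )
    return CombinationDataset(drugs=drugs, combinations=combos)


def filter_dataset(
    ds: CombinationDataset,
    network: InteractionNetwork,
    inhibitory_actions: Iterable[str] = DEFAULT_INHIBITORY_ACTIONS,
) -> CombinationDataset:
    """Restrict drugs to in-network inhibitory targets; drop unusable drugs.

    Per drug, targets are kept only if their action label is inhibitory AND
    the target gene is a node of the analysis network. Drugs with no
    surviving target are removed, along with every combination containing
    them. Idempotent.
    """
    actions = frozenset(str(a).strip().lower() for a in inhibitory_actions)
    kept_drugs: dict[str, DrugRecord] = {}
    for drug_id, rec in ds.drugs.items():
        targets = tuple(
            (g, act) for g, act in rec.targets if act in actions and g in network
        )
        if targets:
            kept_drugs[drug_id] = replace(rec, targets=targets)
    combos = tuple(
        rec for rec in ds.combinations
        if rec.drug_a in kept_drugs and rec.drug_b in kept_drugs
    )
    if not combos:
        raise ValueError("no combinations survive target filtering")
    referenced = {d for rec in combos for d in rec.pair}
    kept_drugs = {d: r for d, r in kept_drugs.items() if d in referenced}
    logger.info(
        "filtered dataset: %d -> %d drugs, %d -> %d combinations",
        len(ds.drugs), len(kept_drugs), ds.n_combinations, len(combos),
    )
    return CombinationDataset(drugs=kept_drugs, combinations=combos)


def synergy_quartiles(
    ds: CombinationDataset, metric: str
) -> tuple[tuple[float, float, float], np.ndarray]:
    """Quartile boundaries (q1, q2, q3) and per-combination quarter labels 1-4.

    Quartiles use the linear-interpolation convention. Quarter membership
    uses half-open intervals with ties at a boundary going to the lower
    quarter, so quarter k spans the k-th quartile interval of the scores.
    """
    _check_metric(metric)
    scores = ds.scores(metric)
    if scores.size < 4:
        raise ValueError("need at least 4 combinations to form quartiles")
    q1, q2, q3 = np.percentile(scores, [25, 50, 75])
    if q1 == q3:
        logger.warning("degenerate synergy distribution for %s: all quartiles equal", metric)
    quarters = 1 + np.searchsorted([q1, q2, q3], scores, side="left")
    return (float(q1), float(q2), float(q3)), quarters.astype(int)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_combination_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path))


def read_drug_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path))


def load_dataset_files(combo_path: str | Path, drug_path: str | Path) -> CombinationDataset:
    return load_dataset(read_combination_table(combo_path), read_drug_table(drug_path))


def write_dataset(ds: CombinationDataset, combo_path: str | Path, drug_path: str | Path) -> None:
    combos = pd.DataFrame(
        [
            {
                "drug_a": r.drug_a, "drug_b": r.drug_b,
                "hsa": r.synergy["HSA"], "zip": r.synergy["ZIP"],
                "bliss": r.synergy["Bliss"], "loewe": r.synergy["Loewe"],
            }
            for r in ds.combinations
        ]
    )
    combos.to_csv(combo_path, sep=_sep(combo_path), index=False)
    rows = [
        {"drug_id": d.drug_id, "name": d.name, "target_gene": g, "action": act}
        for d in ds.drugs.values()
        for g, act in d.targets
    ]
    pd.DataFrame(rows).to_csv(drug_path, sep=_sep(drug_path), index=False)
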