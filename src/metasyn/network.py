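"""Cancer sub-network construction.

Builds a cell-line-specific interaction network from a generic undirected
gene-interaction edge list by (1) restricting to a combined cancer gene set
and (2) removing genes carrying loss-of-function mutations, which are treated
as inactive and unable to transmit signal. After each filtering step, genes
left without any interaction partner are pruned, since downstream
degree-normalized propagation requires every node to have degree >= 1.

Gene symbols are matched exactly after uppercasing and whitespace trimming;
alias resolution is an input-preparation concern and is not attempted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOSS_OF_FUNCTION = "loss_of_function"
GAIN_OF_FUNCTION = "gain_of_function"
UNKNOWN = "unknown"
MUTATION_CATEGORIES = frozenset({LOSS_OF_FUNCTION, GAIN_OF_FUNCTION, UNKNOWN})


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped and uppercased."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (case-normalized, deduplicated)."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(normalize_symbol(s) for s in symbols if str(s).strip()))

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class MutationTable:
    """Per-gene functional mutation categories for one cell line."""

    records: tuple[tuple[str, str], ...]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "MutationTable":
        seen: dict[str, str] = {}
        for gene, category in records:
            gene = normalize_symbol(gene)
            category = str(category).strip().lower()
            if category not in MUTATION_CATEGORIES:
                raise ValueError(
                    f"unknown mutation category {category!r} for gene {gene!r}; "
                    f"expected one of {sorted(MUTATION_CATEGORIES)}"
                )
            if gene in seen and seen[gene] != category:
                raise ValueError(f"conflicting categories for gene {gene!r}")
            seen[gene] = category
        return cls(tuple(sorted(seen.items())))

    def genes_with(self, category: str) -> frozenset[str]:
        return frozenset(g for g, c in self.records if c == category)

    @property
    def lof_genes(self) -> frozenset[str]:
        return self.genes_with(LOSS_OF_FUNCTION)


@dataclass
class InteractionNetwork:
    """Undirected gene-interaction graph with deterministic matrix order.

    Genes are stored in lexicographic order so the adjacency matrix A and the
    degree matrix D are reproducible across runs; these matrices parameterize
    the propagation operator and the graph-Laplacian regularizer downstream.
    """

    genes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    _adjacency: np.ndarray | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        """Build from an iterable of gene-symbol pairs.

        Self-loops and duplicate edges are dropped (with a logged count);
        every retained gene has degree >= 1 by construction.
        """
        clean: set[tuple[str, str]] = set()
        n_self, n_raw = 0, 0
        for a, b in edges:
            n_raw += 1
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                n_self += 1
                continue
            clean.add((a, b) if a < b else (b, a))
        n_dup = n_raw - n_self - len(clean)
        if n_self or n_dup:
            logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
        genes = tuple(sorted({g for e in clean for g in e}))
        return cls(genes=genes, edges=frozenset(clean))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, gene: str) -> int:
        return self._gene_index[normalize_symbol(gene)]

    @property
    def _gene_index(self) -> dict[str, int]:
        idx = getattr(self, "_idx_cache", None)
        if idx is None:
            idx = {g: i for i, g in enumerate(self.genes)}
            object.__setattr__(self, "_idx_cache", idx)
        return idx

    @property
    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix A over the gene order."""
        if self._adjacency is None:
            a = np.zeros((self.n_genes, self.n_genes))
            idx = self._gene_index
            for g1, g2 in self.edges:
                i, j = idx[g1], idx[g2]
                a[i, j] = a[j, i] = 1.0
            self._adjacency = a
        return self._adjacency

    @property
    def degree(self) -> np.ndarray:
        """Per-gene degree vector (diagonal of D), in gene order."""
        return self.adjacency.sum(axis=1)

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian L = D - A."""
        a = self.adjacency
        return np.diag(a.sum(axis=1)) - a

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self._gene_index

    def validate(self) -> None:
        if any(a == b for a, b in self.edges):
            raise ValueError("network contains a self-loop")
        deg = self.degree
        if self.n_genes and deg.min() < 1:
            raise ValueError("network contains an isolated gene")


def merge_gene_sets(sets: Sequence[GeneSet]) -> GeneSet:
    """Union of cancer-related gene sets into one combined list."""
    if not sets:
        raise ValueError("merge_gene_sets requires at least one gene set")
    symbols: frozenset[str] = frozenset().union(*(s.symbols for s in sets))
    name = "+".join(s.name for s in sets)
    return GeneSet(name=name, symbols=symbols)


def induce_subnetwork(network: InteractionNetwork, keep: GeneSet) -> InteractionNetwork:
    """Keep only edges whose both endpoints are in ``keep``; prune isolated genes."""
    kept_edges = [(a, b) for a, b in network.edges if a in keep.symbols and b in keep.symbols]
    if not kept_edges:
        raise ValueError(
            "induced sub-network is empty: no edge has both endpoints in the gene set"
        )
    result = InteractionNetwork.from_edges(kept_edges)
    logger.info(
        "induced sub-network: %d -> %d genes, %d -> %d edges",
        network.n_genes, result.n_genes, network.n_edges, result.n_edges,
    )
    return result


def remove_lof_genes(
    network: InteractionNetwork, mutations: MutationTable
) -> InteractionNetwork:
    """Delete loss-of-function genes and their interactions; prune isolated genes.

    Gain-of-function and unknown-category genes are retained. An empty
    mutation table (or one without LoF records) returns the input unchanged.
    """
    lof = mutations.lof_genes
    if not lof & set(network.genes):
        return network
    kept_edges = [(a, b) for a, b in network.edges if a not in lof and b not in lof]
    if not kept_edges:
        # e.g. a star whose center is LoF: every remaining gene is isolated
        return InteractionNetwork(genes=(), edges=frozenset())
    result = InteractionNetwork.from_edges(kept_edges)
    logger.info(
        "removed %d LoF genes: %d -> %d genes, %d -> %d edges",
        len(lof & set(network.genes)),
        network.n_genes, result.n_genes, network.n_edges, result.n_edges,
    )
    return result


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _delimiter_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_edge_list(path: str | Path, header: bool | None = None) -> InteractionNetwork:
    """Read a 2-column delimited edge list (TSV/CSV by extension).

    ``header=None`` auto-detects: if the first row repeats anywhere or looks
    like column labels (e.g. ``gene1``), it is treated as a header.
    """
    sep = _delimiter_for(path)
    if header is None:
        first = pd.read_csv(path, sep=sep, nrows=1, header=None)
        looks_like = any(
            str(v).strip().lower() in {"gene1", "gene2", "gene_a", "gene_b", "source", "target"}
            for v in first.iloc[0]
        )
        header = looks_like
    df = pd.read_csv(path, sep=sep, header=0 if header else None, usecols=[0, 1])
    return InteractionNetwork.from_edges(df.itertuples(index=False, name=None))


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    sep = _delimiter_for(path)
    df = pd.DataFrame(sorted(network.edges), columns=["gene1", "gene2"])
    df.to_csv(path, sep=sep, index=False)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene-set file."""
    symbols = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return GeneSet.from_symbols(name or Path(path).stem, symbols)


def read_mutation_table(path: str | Path) -> MutationTable:
    df = pd.read_csv(path, sep=_delimiter_for(path))
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "category" not in cols:
        raise ValueError("mutation table must have columns 'gene' and 'category'")
    return MutationTable.from_records(
        zip(df[cols["gene"]].astype(str), df[cols["category"]].astype(str))
    )
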