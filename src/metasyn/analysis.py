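"""Downstream statistics linking propagated profiles and metagenes to synergy.

The analyses here answer, in order: (1) which individual genes' propagated
scores separate the least- from the most-synergistic quartile of drug
combinations (rank-sum screen with FDR control, plus Spearman correlations);
(2) which clusters of combinations — Ward-D2 hierarchical clustering of the
metagene-loading matrix H — are enriched for high synergy, by scanning every
dendrogram cut and keeping clusters whose mean score exceeds the global
third quartile for at least one metric, one representative per nested
lineage; (3) whether a single metagene dominates the loading profiles of the
enriched clusters (paired one-sided signed-rank tests, FDR-adjusted); and
(4) per-drug follow-ups: a two-group split of one drug's combinations by
metagene loading with one-sided Welch t-tests on synergy, and a one-sample
signed-rank test of whether a partner drug's combinations are synergistic at
all.

Rank-based tests use exact null distributions for small samples (n <= 25,
no ties) and the normal approximation with continuity correction otherwise;
"FDR" is Benjamini-Hochberg throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .dataset import SYNERGY_METRICS, CombinationDataset, synergy_quartiles
from .propagation import ProfileMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    screen_alpha: float = 1e-4      # adjusted-p cutoff for the gene screen
    fdr_q: float = 0.05             # adjusted-p cutoff for all other tests
    min_cluster_size: int = 10
    enrichment_quantile: float = 0.75  # Q3

    def __post_init__(self) -> None:
        for name in ("screen_alpha", "fdr_q", "enrichment_quantile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Gene-level screens
# ---------------------------------------------------------------------------

def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) statistic and p-value."""
    if np.ptp(np.concatenate([x, y])) == 0:
        return 0.5 * len(x) * len(y), 1.0  # no separation possible
    pooled = np.concatenate([x, y])
    exact = len(x) <= 25 and len(y) <= 25 and len(np.unique(pooled)) == pooled.size
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class GeneScreenResult:
    """Per-gene quartile-contrast screen for one synergy metric."""

    metric: str
    table: pd.DataFrame  # gene, statistic, p, p_adj, significant
    quartiles: tuple[float, float, float]
    quarters: np.ndarray  # per-combination quarter labels 1..4

    @property
    def significant_genes(self) -> list[str]:
        t = self.table
        return t.loc[t["significant"], "gene"].tolist()

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def quartile_gene_screen(
    x: ProfileMatrix,
    ds: CombinationDataset,
    metric: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> GeneScreenResult:
    """Rank-sum contrast of propagated scores: bottom vs top synergy quartile.

    For every gene, compares the propagated scores of the combinations in
    the first quarter (bottom 25% of the chosen synergy metric) against the
    fourth quarter (top 25%) with a two-sided Wilcoxon rank-sum test;
    p-values are BH-adjusted across all genes and flagged significant below
    ``config.screen_alpha``. Being rank-based, the screen is invariant to
    any strictly monotone transform of the scores.
    """
    quartiles, quarters = synergy_quartiles(ds, metric)
    lo = np.flatnonzero(quarters == 1)
    hi = np.flatnonzero(quarters == 4)
    if lo.size == 0 or hi.size == 0:
        raise ValueError("both extreme quarters must be non-empty")
    stats = np.empty(x.n_genes)
    pvals = np.empty(x.n_genes)
    for i in range(x.n_genes):
        stats[i], pvals[i] = _ranksum_p(x.matrix[i, lo], x.matrix[i, hi])
    p_adj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "gene": list(x.genes),
            "statistic": stats,
            "p": pvals,
            "p_adj": p_adj,
            "significant": p_adj < config.screen_alpha,
        }
    ).sort_values("p_adj", kind="stable", ignore_index=True)
    return GeneScreenResult(metric=metric, table=table, quartiles=quartiles, quarters=quarters)


def gene_synergy_correlation(
    x: ProfileMatrix,
    ds: CombinationDataset,
    genes: Iterable[str],
    metric: str,
) -> pd.DataFrame:
    """Spearman rho between each gene's propagated scores and a synergy metric.

    Computed over all combinations; p-values use the t approximation and are
    BH-adjusted across exactly the requested genes. Genes with constant
    propagated scores have undefined rho and are reported as missing.
    """
    scores = ds.scores(metric)
    rows = []
    for gene in genes:
        prop = x.gene_row(gene)
        if np.ptp(prop) == 0 or np.ptp(scores) == 0:
            rows.append((gene, np.nan, np.nan))
            continue
        rho, p = scipy.stats.spearmanr(prop, scores)
        rows.append((gene, float(rho), float(p)))
    df = pd.DataFrame(rows, columns=["gene", "rho", "p"])
    df["p_adj"] = bh_adjust(df["p"])
    return df


# ---------------------------------------------------------------------------
# Clustering and enrichment
# ---------------------------------------------------------------------------

def hierarchical_cluster(h: np.ndarray) -> np.ndarray:
    """Ward-D2 dendrogram over the columns of H under Euclidean distance.

    Returns a scipy linkage matrix with M - 1 merges and non-decreasing
    heights (Ward linkage is monotone).
    """
    h = np.asarray(h, float)
    if h.ndim != 2 or h.shape[1] < 2:
        raise ValueError("H must be 2-D with at least 2 columns")
    return sch.linkage(h.T, method="ward")


@dataclass(frozen=True)
class ClusterCandidate:
    """One dendrogram cluster enriched for high synergy."""

    members: frozenset[int]          # combination indices
    cut_height: float
    means: Mapping[str, float]       # per-metric mean synergy of members
    sds: Mapping[str, float]
    qualifying: tuple[str, ...]      # metrics whose mean exceeds the global Q3

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def best_qualifying_mean(self) -> float:
        return max(self.means[m] for m in self.qualifying)


def global_q3(ds: CombinationDataset, quantile: float = 0.75) -> dict[str, float]:
    """Per-metric enrichment threshold over all retained combinations."""
    return {m: float(np.quantile(ds.scores(m), quantile)) for m in SYNERGY_METRICS}


def enumerate_enriched_clusters(
    linkage: np.ndarray,
    ds: CombinationDataset,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[ClusterCandidate]:
    """Scan every dendrogram partition for clusters of high mean synergy.

    The dendrogram is cut at every height that creates a new partition; in
    each partition, every cluster with at least ``min_cluster_size`` members
    whose mean synergy exceeds the global Q3 threshold for at least one
    metric becomes a candidate. Identical member sets arising from several
    cuts are collapsed, keeping the lowest qualifying cut height.
    """
    m = linkage.shape[0] + 1
    thresholds = global_q3(ds, config.enrichment_quantile)
    score_arrays = {metric: ds.scores(metric) for metric in SYNERGY_METRICS}
    heights = {n_clusters: float(linkage[m - 1 - n_clusters, 2]) for n_clusters in range(1, m)}
    heights[m] = 0.0
    seen: dict[frozenset[int], ClusterCandidate] = {}
    for n_clusters in range(1, m + 1):
        labels = sch.cut_tree(linkage, n_clusters=n_clusters).ravel()
        for lab in np.unique(labels):
            members = frozenset(np.flatnonzero(labels == lab).tolist())
            if len(members) < config.min_cluster_size:
                continue
            if members in seen:
                prev = seen[members]
                if heights[n_clusters] < prev.cut_height:
                    seen[members] = ClusterCandidate(
                        members, heights[n_clusters], prev.means, prev.sds, prev.qualifying
                    )
                continue
            idx = sorted(members)
            means = {met: float(np.mean(s[idx])) for met, s in score_arrays.items()}
            sds = {met: float(np.std(s[idx], ddof=1)) for met, s in score_arrays.items()}
            qualifying = tuple(met for met in SYNERGY_METRICS if means[met] > thresholds[met])
            if qualifying:
                seen[members] = ClusterCandidate(
                    members, heights[n_clusters], means, sds, qualifying
                )
    out = sorted(seen.values(), key=lambda c: (-c.best_qualifying_mean, sorted(c.members)))
    logger.info("found %d unique enriched cluster candidates", len(out))
    return out


def dedup_lineages(candidates: Sequence[ClusterCandidate]) -> list[ClusterCandidate]:
    """Keep one representative per nested lineage of candidate clusters.

    Lineages are connected components of the subset-comparability graph on
    member sets; within each lineage the candidate with the highest best
    qualifying mean synergy is retained, so the output is pairwise
    non-nested.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = candidates[i].members, candidates[j].members
            if a <= b or b <= a:
                parent[find(i)] = find(j)
    groups: dict[int, list[ClusterCandidate]] = {}
    for i, cand in enumerate(candidates):
        groups.setdefault(find(i), []).append(cand)
    final = [
        min(grp, key=lambda c: (-c.best_qualifying_mean, sorted(c.members)))
        for grp in groups.values()
    ]
    return sorted(final, key=lambda c: (-c.best_qualifying_mean, sorted(c.members)))


def most_frequent_drug(
    cluster: ClusterCandidate, ds: CombinationDataset
) -> tuple[str, int]:
    """The drug appearing in the most member pairs (ties lexicographic)."""
    counts: dict[str, int] = {}
    for i in cluster.members:
        for d in ds.combinations[i].pair:
            counts[d] = counts.get(d, 0) + 1
    drug = min(counts, key=lambda d: (-counts[d], d))
    return drug, counts[drug]


def cluster_report(
    final_clusters: Sequence[ClusterCandidate], ds: CombinationDataset
) -> pd.DataFrame:
    """Tabular report: one row per final cluster with qualifying statistics."""
    rows = []
    for cid, c in enumerate(final_clusters, start=1):
        drug, count = most_frequent_drug(c, ds)
        row: dict[str, object] = {
            "cluster_id": cid,
            "cut_height": round(c.cut_height, 2),
            "n_pairs": c.size,
        }
        for met in SYNERGY_METRICS:
            row[met] = (
                f"{c.means[met]:.2f} +/- {c.sds[met]:.2f}" if met in c.qualifying else ""
            )
        row["most_frequent_drug"] = drug
        row["n_pairs_with_drug"] = count
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metagene-level tests
# ---------------------------------------------------------------------------

def _signed_rank_p(diff: np.ndarray) -> float:
    """One-sided signed-rank p for median(diff) > 0, zeros dropped."""
    diff = diff[diff != 0]
    if diff.size == 0:
        return 1.0
    exact = diff.size <= 25 and np.unique(np.abs(diff)).size == diff.size
    res = scipy.stats.wilcoxon(
        diff,
        alternative="greater",
        zero_method="wilcox",
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return float(res.pvalue)


def metagene_dominance_test(
    h: np.ndarray,
    final_clusters: Sequence[ClusterCandidate],
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Does one metagene's loading exceed every other metagene's?

    Pools the member combinations of all final clusters (deduplicated), and
    for each metagene runs a one-sided paired Wilcoxon signed-rank test
    against each of the other K - 1 metagenes, BH-adjusting within the
    comparison family. A metagene dominates when every adjusted p-value is
    below ``config.fdr_q``; the reported ``max_adj_p`` is the worst of them.
    """
    h = np.asarray(h, float)
    k = h.shape[0]
    if k < 2:
        raise ValueError("dominance test requires at least 2 metagenes")
    if not final_clusters:
        raise ValueError("dominance test requires at least one final cluster")
    pooled = sorted(set().union(*(c.members for c in final_clusters)))
    rows = []
    for kk in range(k):
        pvals = [
            _signed_rank_p(h[kk, pooled] - h[jj, pooled]) for jj in range(k) if jj != kk
        ]
        adj = bh_adjust(pvals)
        rows.append(
            {
                "metagene": kk,
                "max_adj_p": float(np.max(adj)),
                "dominant": bool(np.all(adj < config.fdr_q)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DrugSplitResult:
    """Two-group split of one drug's combinations by metagene loading."""

    drug: str
    metagene: int
    high_group: tuple[int, ...]  # combination indices, higher tested-metagene mean
    low_group: tuple[int, ...]
    pvalues: Mapping[str, float]  # one-sided Welch t-test, high > low, per metric
    degenerate: bool = False


def split_drug_combinations(
    h: np.ndarray,
    ds: CombinationDataset,
    drug: str,
    metagene: int,
    config: AnalysisConfig = AnalysisConfig(),
) -> DrugSplitResult:
    """Cluster one drug's combinations into two groups and test their synergy.

    The drug's H columns are split in two by Ward-D2/Euclidean clustering;
    the group with the higher mean loading on the tested metagene is labelled
    "high". Per synergy metric, a one-sided Welch t-test asks whether the
    high group's scores exceed the low group's.
    """
    idx = ds.combinations_with(drug)
    if len(idx) < 4:
        raise ValueError(f"drug {drug!r} appears in only {len(idx)} combinations; need >= 4")
    cols = np.asarray(h, float)[:, idx]
    degenerate = bool(np.allclose(cols, cols[:, :1]))
    linkage = sch.linkage(cols.T, method="ward")
    labels = sch.fcluster(linkage, t=2, criterion="maxclust")
    if len(np.unique(labels)) < 2:
        # identical columns: fall back to an arbitrary half split
        labels = np.ones(len(idx), int)
        labels[: len(idx) // 2] = 2
        degenerate = True
    if degenerate:
        logger.warning("H columns for drug %s are (near-)identical; split is arbitrary", drug)
    g1 = [idx[i] for i in range(len(idx)) if labels[i] == 1]
    g2 = [idx[i] for i in range(len(idx)) if labels[i] == 2]
    h_row = np.asarray(h, float)[metagene]
    if h_row[g1].mean() >= h_row[g2].mean():
        high, low = g1, g2
    else:
        high, low = g2, g1
    pvalues = {}
    for met in SYNERGY_METRICS:
        s = ds.scores(met)
        res = scipy.stats.ttest_ind(s[high], s[low], equal_var=False, alternative="greater")
        p = float(res.pvalue)
        pvalues[met] = 0.5 if np.isnan(p) else p
    return DrugSplitResult(
        drug=drug, metagene=metagene, high_group=tuple(high), low_group=tuple(low),
        pvalues=pvalues, degenerate=degenerate,
    )


def partner_drug_test(
    ds: CombinationDataset,
    drugs: Sequence[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Are a partner drug's combinations synergistic at all?

    For each (drug, metric) cell, a one-sided one-sample Wilcoxon
    signed-rank test of whether that drug's combination scores exceed zero;
    BH adjustment is applied across all tested cells jointly.
    """
    rows = []
    for drug in drugs:
        idx = ds.combinations_with(drug)
        if not idx:
            raise ValueError(f"drug {drug!r} has no combinations")
        for met in SYNERGY_METRICS:
            scores = ds.scores(met)[list(idx)]
            rows.append({"drug": drug, "metric": met, "n": len(idx),
                         "p": _signed_rank_p(scores)})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"])
    df["significant"] = df["p_adj"] < config.fdr_q
    return df
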