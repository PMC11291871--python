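"""Gene-abundance statistics: GPM normalization, grouped comparisons and
the presence/absence co-occurrence network.

GPM (genes per million) normalizes mapped read counts by gene length and by
the per-sample total of length-normalized counts,

    GPM_k = (r_k / l_k) / sum_i (r_i / l_i) * 1e6,

with r_i the reads mapped to gene i and l_i its length — arithmetically the
same scheme as TPM in transcriptomics.  Every sample column with at least
one mapped read sums to exactly one million.

Group comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney U)
test per gene row, reported with both Benjamini-Hochberg (FDR) and
Bonferroni adjustments; significance stars are keyed to the FDR-adjusted
p at the 0.1 / 0.05 / 0.01 / 0.001 levels.

The co-occurrence network connects two genes when their binary Jaccard
similarity across MAGs (|intersection| / |union| of the MAG sets carrying
them) strictly exceeds a threshold, 0.3 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import GeneCountTable, SampleInfo, TableError, logger

#: FDR-adjusted p-value thresholds and their significance codes.
SIGNIFICANCE_CODES = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))

#: Largest group size for which the exact rank-sum distribution is used.
EXACT_LIMIT = 8


@dataclass(frozen=True)
class GpmTable:
    """Genes-per-million normalized gene abundances (genes x samples).

    ``complete`` marks a table covering every gene of its sample, for which
    each non-empty column must sum to one million; aggregated subsets
    (e.g. rows summed into KO groups over a partial grouping) set it False.
    """

    gpm: pd.DataFrame
    complete: bool = True

    def __post_init__(self) -> None:
        arr = self.gpm.to_numpy()
        if (arr < 0).any():
            raise TableError("GPM values must be non-negative")
        if self.complete:
            sums = arr.sum(axis=0)
            nonzero = sums > 0
            if not np.allclose(sums[nonzero], 1e6, rtol=1e-9, atol=0):
                raise TableError("non-empty GPM columns must sum to 1e6")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.gpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.gpm.columns)


@dataclass(frozen=True)
class GeneComparison:
    """Rank-sum comparison of one gene (or gene group) between two groups."""

    gene_id: str
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adj_bh: float
    p_adj_bonferroni: float
    significance_code: str


COMPARISON_COLUMNS = [
    "gene_id", "group_a", "group_b", "statistic",
    "p_raw", "p_adj_bh", "p_adj_bonferroni", "significance_code",
]


def comparison_records(comparisons: Sequence[GeneComparison]) -> list[dict]:
    return [c.__dict__ for c in comparisons]


def gpm_normalize(counts: GeneCountTable) -> GpmTable:
    """Normalize read counts to genes-per-million.

    A sample with zero mapped reads is emitted as an all-zero column with a
    warning rather than dividing 0 by 0.
    """
    rates = counts.counts.to_numpy(dtype=float) / counts.lengths_bp.to_numpy()[:, None]
    totals = rates.sum(axis=0)
    empty = totals == 0
    if empty.any():
        logger.warning(
            "samples with zero mapped reads emitted as all-zero GPM columns: %s",
            [s for s, e in zip(counts.sample_ids, empty) if e],
        )
    totals = np.where(empty, 1.0, totals)
    gpm = rates / totals * 1e6
    return GpmTable(pd.DataFrame(gpm, index=counts.gene_ids, columns=counts.sample_ids))


def aggregate_genes(gpm: GpmTable, grouping: Mapping[str, str]) -> GpmTable:
    """Sum member-gene GPM per functional group (e.g. KO or module) label.

    Genes absent from ``grouping`` are dropped (their count is logged);
    group rows appear in first-member order.
    """
    if not grouping:
        raise TableError("empty gene grouping")
    member = {g: grouping[g] for g in gpm.gene_ids if g in grouping}
    dropped = len(gpm.gene_ids) - len(member)
    if dropped:
        logger.info("aggregate_genes: %d ungrouped genes dropped", dropped)
    if not member:
        raise TableError("grouping covers none of the table's genes")
    labels = pd.Series(member, name="group")
    agg = gpm.gpm.loc[labels.index].groupby(labels, sort=False).sum()
    agg.index.name = None
    return GpmTable(agg, complete=False)


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small tie-free groups."""
    if np.ptp(np.concatenate([x, y])) == 0:
        # identical constant data carries no ordering information
        return float(len(x) * len(y) / 2.0), 1.0
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= EXACT_LIMIT and len(y) <= EXACT_LIMIT and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def significance_code(p_adj_bh: float) -> str:
    for threshold, code in SIGNIFICANCE_CODES:
        if p_adj_bh < threshold:
            return code
    return ""


def compare_groups(
    gpm: GpmTable,
    samples: Sequence[SampleInfo],
    pairs: Sequence[tuple[str, str]],
) -> list[GeneComparison]:
    """Rank-sum tests per gene row for each requested group-label pair.

    Multiple-testing adjustment (BH and Bonferroni) is applied across the
    gene rows *within* each group pair.  Rows that are all-zero in both
    groups are skipped — degenerate tests would only inflate the burden.
    Comparisons where either group has fewer than two samples are skipped
    with a warning.
    """
    group_samples: dict[str, list[str]] = {}
    for s in samples:
        group_samples.setdefault(s.group, []).append(s.sample_id)

    out: list[GeneComparison] = []
    for group_a, group_b in pairs:
        for g in (group_a, group_b):
            if g not in group_samples:
                raise TableError(f"unknown group label {g!r}")
        cols_a = [s for s in group_samples[group_a] if s in gpm.gpm.columns]
        cols_b = [s for s in group_samples[group_b] if s in gpm.gpm.columns]
        if len(cols_a) < 2 or len(cols_b) < 2:
            logger.warning(
                "comparison %s vs %s skipped: fewer than 2 samples per group",
                group_a, group_b,
            )
            continue
        a = gpm.gpm[cols_a].to_numpy()
        b = gpm.gpm[cols_b].to_numpy()
        keep = ~((a == 0).all(axis=1) & (b == 0).all(axis=1))
        genes = [g for g, k in zip(gpm.gene_ids, keep) if k]
        results = [_rank_sum(a[i], b[i]) for i in np.nonzero(keep)[0]]
        if not results:
            continue
        stats_, p_raw = zip(*results)
        p_bh = multipletests(p_raw, method="fdr_bh")[1]
        p_bonf = multipletests(p_raw, method="bonferroni")[1]
        out.extend(
            GeneComparison(
                gene_id=g,
                group_a=group_a,
                group_b=group_b,
                statistic=s,
                p_raw=p,
                p_adj_bh=float(bh),
                p_adj_bonferroni=float(bf),
                significance_code=significance_code(float(bh)),
            )
            for g, s, p, bh, bf in zip(genes, stats_, p_raw, p_bh, p_bonf)
        )
    return out


def cooccurrence_network(presence: pd.DataFrame, threshold: float = 0.3) -> nx.Graph:
    """Gene co-occurrence graph from a gene-by-MAG presence/absence matrix.

    The co-occurrence level of two genes is their binary Jaccard similarity
    over MAG sets; an edge is drawn when the level strictly exceeds
    ``threshold``.  Genes carried by no MAG remain isolated nodes.
    """
    if not (0 <= threshold < 1):
        raise TableError(f"threshold must lie in [0, 1), got {threshold}")
    arr = presence.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise TableError("presence matrix must be binary (0/1)")
    arr = arr.astype(float)
    inter = arr @ arr.T
    sizes = arr.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)

    graph = nx.Graph()
    graph.add_nodes_from(presence.index)
    genes = list(presence.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    for i, j in zip(iu, ju):
        if level[i, j] > threshold:
            graph.add_edge(genes[i], genes[j], weight=float(level[i, j]))
    return graph
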