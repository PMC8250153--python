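"""Chromosome-level silencing profile from a DE result table.

Implements the downstream analysis used to localize transgene-induced
silencing: threshold filtering of differentially expressed genes,
per-chromosome down/up counts and percentages, single-linkage proximity
clustering of down-regulated genes within a megabase window, a
three-criterion composite ranking of candidate chromosomes, group-mean
expression-reduction percentages, and genomic gaps between clusters.

Genomic coordinates are 1-based inclusive throughout this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))


REQUIRED_FILTER_COLUMNS = ("gene_id", "chrom", "log2fc", "adj_p")

#: Default thresholds of the stringent DE filter.
DEFAULT_P_CUTOFF = 0.01
DEFAULT_LFC_CUTOFF = 1.0
#: Relaxed alternative fold-change cutoff.
RELAXED_LFC_CUTOFF = 0.5
#: Down-regulated genes closer than this on one chromosome are clustered.
DEFAULT_WINDOW_BP = 5_000_000
#: Candidate chromosomes need at least this many clustered down genes.
DEFAULT_MIN_CLUSTERED = 4


@dataclass
class GeneCluster:
    """A maximal chain of >=2 down-regulated genes linked at < window bp."""

    chrom: str
    members: list[str]
    span_start: int
    span_end: int

    def __len__(self) -> int:
        return len(self.members)

    @property
    def span_bp(self) -> int:
        return self.span_end - self.span_start + 1


def _require_columns(table: pd.DataFrame, columns) -> None:
    for col in columns:
        if col not in table.columns:
            raise ValueError(f"DE table is missing required column {col!r}")


def filter_de_genes(
    table: pd.DataFrame,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a DE table into (down, up) gene sets.

    A gene is called down when ``adj_p < p_cutoff`` and
    ``log2fc <= -lfc_cutoff``; up when ``adj_p < p_cutoff`` and
    ``log2fc >= +lfc_cutoff``.  The p comparison is strict, the
    fold-change comparison inclusive.
    """
    if p_cutoff <= 0 or lfc_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    _require_columns(table, REQUIRED_FILTER_COLUMNS)
    sig = table["adj_p"] < p_cutoff
    down = table[sig & (table["log2fc"] <= -lfc_cutoff)].copy()
    up = table[sig & (table["log2fc"] >= lfc_cutoff)].copy()
    return down, up


def per_chromosome_counts(
    down: pd.DataFrame, up: pd.DataFrame, full_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-chromosome DE counts and percentages.

    ``pct_down`` uses the number of genes of that chromosome present in
    the input table as its denominator, so the statistic is
    self-contained rather than tied to an external annotation release.
    Chromosomes with zero DE genes are still reported.
    """
    _require_columns(full_table, ("gene_id", "chrom"))
    totals = full_table.groupby("chrom")["gene_id"].count()
    chroms = sorted(totals.index, key=_chrom_sort_key)
    n_down = down.groupby("chrom")["gene_id"].count() if len(down) else pd.Series(dtype=int)
    n_up = up.groupby("chrom")["gene_id"].count() if len(up) else pd.Series(dtype=int)
    rows = []
    for chrom in chroms:
        nt = int(totals[chrom])
        nd = int(n_down.get(chrom, 0))
        rows.append(
            {
                "chrom": chrom,
                "n_down": nd,
                "n_up": int(n_up.get(chrom, 0)),
                "n_total_genes": nt,
                "pct_down": 100.0 * nd / nt if nt else 0.0,
            }
        )
    return pd.DataFrame(rows)


def proximity_clusters(
    down: pd.DataFrame,
    window: int = DEFAULT_WINDOW_BP,
    anchor: str = "start",
) -> tuple[list[GeneCluster], list[str]]:
    """Single-linkage proximity clusters of down-regulated genes.

    Two genes on the same chromosome link when their anchor positions
    differ by strictly less than ``window`` bp; clusters are the
    connected components with >=2 members, so a cluster may span more
    than one window through intermediates.  Returns ``(clusters,
    unclustered gene ids)``.  The anchor is the gene ``start`` by
    default (``"midpoint"`` uses (start+end)/2 and requires ``end``).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if anchor not in ("start", "midpoint"):
        raise ValueError("anchor must be 'start' or 'midpoint'")
    _require_columns(down, ("gene_id", "chrom", "start"))
    if anchor == "midpoint":
        _require_columns(down, ("end",))

    clusters: list[GeneCluster] = []
    unclustered: list[str] = []
    for chrom in sorted(down["chrom"].unique(), key=_chrom_sort_key):
        sub = down[down["chrom"] == chrom]
        pos = (
            sub["start"].to_numpy(float)
            if anchor == "start"
            else (sub["start"].to_numpy(float) + sub["end"].to_numpy(float)) / 2.0
        )
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        ids = sub["gene_id"].to_numpy()[order]
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order] if "end" in sub.columns else starts
        # on sorted 1-D anchors single linkage reduces to chaining
        # consecutive genes whose gap is < window
        run = [0]
        for i in range(1, len(pos)):
            if pos[i] - pos[i - 1] < window:
                run.append(i)
            else:
                _close_run(run, ids, starts, ends, chrom, clusters, unclustered)
                run = [i]
        if len(pos):
            _close_run(run, ids, starts, ends, chrom, clusters, unclustered)
    return clusters, unclustered


def _close_run(run, ids, starts, ends, chrom, clusters, unclustered) -> None:
    if len(run) >= 2:
        clusters.append(
            GeneCluster(
                chrom=chrom,
                members=[str(ids[i]) for i in run],
                span_start=int(min(starts[i] for i in run)),
                span_end=int(max(ends[i] for i in run)),
            )
        )
    else:
        unclustered.append(str(ids[run[0]]))


def count_clustered_by_chrom(clusters: list[GeneCluster]) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in clusters:
        out[c.chrom] = out.get(c.chrom, 0) + len(c)
    return out


def rank_chromosomes(
    summaries: pd.DataFrame, min_clustered: int = DEFAULT_MIN_CLUSTERED
) -> pd.DataFrame:
    """Composite ranking of candidate silenced chromosomes.

    Each chromosome is ranked (descending, average ranks on ties) on
    three criteria — number of down-regulated genes, percentage of the
    chromosome's genes that are down-regulated, and number of
    down-regulated genes lying in proximity clusters — and ordered by
    the mean of the three ranks.  Chromosomes with fewer than
    ``min_clustered`` clustered down genes are flagged ``excluded`` but
    retained in the report.  Ties break by higher ``pct_down``, then by
    chromosome id.  The result is independent of input row order.
    """
    required = ("chrom", "n_down", "pct_down", "n_clustered_down")
    _require_columns(summaries, required)
    df = summaries.copy()
    for crit in ("n_down", "pct_down", "n_clustered_down"):
        df[f"rank_{crit}"] = rankdata(-df[crit].to_numpy(float), method="average")
    df["composite_rank"] = df[["rank_n_down", "rank_pct_down", "rank_n_clustered_down"]].mean(axis=1)
    df["excluded"] = df["n_clustered_down"] < min_clustered
    df["_key"] = df["chrom"].map(_chrom_sort_key)
    df = df.sort_values(
        by=["composite_rank", "pct_down", "_key"],
        ascending=[True, False, True],
        kind="stable",
    ).drop(columns="_key")
    return df.reset_index(drop=True)


def top_candidates(ranked: pd.DataFrame, n: int = 2) -> list[str]:
    """The top non-excluded chromosomes of a ranking report."""
    return list(ranked.loc[~ranked["excluded"], "chrom"].head(n))


def expression_reduction(fpkm_wt: float, fpkm_tg: float) -> float:
    """Percent expression reduction in TG relative to WT group-mean FPKM.

    ``100 * (1 - fpkm_tg / fpkm_wt)``; negative for up-regulated genes.
    """
    if fpkm_wt <= 0:
        raise ValueError("expression reduction undefined for fpkm_wt <= 0")
    return 100.0 * (1.0 - fpkm_tg / fpkm_wt)


def cluster_gap(cluster_a: GeneCluster, cluster_b: GeneCluster) -> int:
    """Genomic gap in bp between two non-overlapping clusters.

    With 1-based inclusive spans the gap is ``downstream start −
    upstream end``, so spans [1–10] and [11–20] are 1 bp apart and
    spans sharing a boundary base are 0 apart.  Overlapping spans give
    0 with a warning.
    """
    if cluster_a.chrom != cluster_b.chrom:
        raise ValueError(
            f"clusters on different chromosomes: {cluster_a.chrom!r} vs {cluster_b.chrom!r}"
        )
    first, second = sorted((cluster_a, cluster_b), key=lambda c: c.span_start)
    gap = second.span_start - first.span_end
    if gap < 0:
        warnings.warn("cluster spans overlap; reporting gap 0", stacklevel=2)
        return 0
    return int(gap)


def profile_de_table(
    table: pd.DataFrame,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
    window: int = DEFAULT_WINDOW_BP,
    min_clustered: int = DEFAULT_MIN_CLUSTERED,
) -> dict:
    """Run the full silencing profile and return its report bundle."""
    down, up = filter_de_genes(table, p_cutoff, lfc_cutoff)
    summaries = per_chromosome_counts(down, up, table)
    clusters, unclustered = proximity_clusters(down, window)
    clustered_counts = count_clustered_by_chrom(clusters)
    summaries["n_clustered_down"] = summaries["chrom"].map(
        lambda c: clustered_counts.get(c, 0)
    )
    ranked = rank_chromosomes(summaries, min_clustered)
    return {
        "down": down,
        "up": up,
        "summaries": summaries,
        "clusters": clusters,
        "unclustered": unclustered,
        "ranking": ranked,
        "candidates": top_candidates(ranked),
    }
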