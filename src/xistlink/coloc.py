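"""Xic-spot / chromosome-paint co-localization scoring and linkage calls.

A cell's co-localization count is the number of Xic pinpoint spots that
can be credited to distinct painted territories of one chromosome: a
spot is eligible for a territory when its distance to the territory
centre is at most the territory radius plus a configurable margin, and
each territory may be credited by at most one spot (maximum bipartite
matching).  Condition summaries tabulate per-cell counts and the
percentage of cells reaching k >= 1 and k >= 2 co-localizations; pairs
of conditions are compared with Fisher's exact test on the binary
"k >= threshold" collapse.  A chromosome is called genetically linked
to the transgene when its TG co-localization frequency is statistically
indistinguishable from the positive control (Xic on Chr X) and exceeds
every other candidate autosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import fisher_exact

from .simulate import XIC, Nucleus

PCT_THRESHOLDS = (1, 2)


@dataclass
class CellColocRecord:
    cell_id: str
    genotype: str
    paint_chromosome: str
    n_xic_spots: int
    n_coloc: int


@dataclass
class ColocalizationSummary:
    """Distribution of per-cell co-localization counts for one condition."""

    genotype: str
    paint_chromosome: str
    n_cells: int
    counts_by_k: dict[int, int]
    pct_at_least: dict[int, float]

    @property
    def condition(self) -> tuple[str, str]:
        return (self.genotype, self.paint_chromosome)


@dataclass
class LinkageCall:
    chrom: str
    linked: bool
    p_vs_reference: float
    p_vs_controls: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def score_cell(
    nucleus: Nucleus, paint_chromosome: str, margin: float = 0.0
) -> CellColocRecord:
    """Count Xic spots co-localizing with painted territories of one
    chromosome, each territory creditable by at most one spot."""
    xic = nucleus.spots_in_channel(XIC)
    if not xic:
        raise ValueError(f"nucleus {nucleus.cell_id} has no Xic spots")
    territories = nucleus.territories_of(paint_chromosome)
    if not territories:
        raise ValueError(
            f"nucleus {nucleus.cell_id} has no territories for chromosome "
            f"{paint_chromosome!r}"
        )
    spots = np.array([s.xyz for s in xic])
    centers = np.array([t.center for t in territories])
    radii = np.array([t.radius for t in territories])
    dist = np.linalg.norm(spots[:, None, :] - centers[None, :, :], axis=2)
    eligible = (dist <= radii[None, :] + margin).astype(float)
    # max bipartite matching via assignment on the 0/1 eligibility matrix
    rows, cols = linear_sum_assignment(eligible, maximize=True)
    n_coloc = int(eligible[rows, cols].sum())
    return CellColocRecord(
        cell_id=nucleus.cell_id,
        genotype=nucleus.genotype,
        paint_chromosome=paint_chromosome,
        n_xic_spots=len(xic),
        n_coloc=n_coloc,
    )


def summarize_condition(records: list[CellColocRecord]) -> ColocalizationSummary:
    """Tabulate co-localization counts for one (genotype, paint) condition."""
    if not records:
        raise ValueError("cannot summarize an empty set of cells")
    conditions = {(r.genotype, r.paint_chromosome) for r in records}
    if len(conditions) > 1:
        raise ValueError(f"records span multiple conditions: {sorted(conditions)}")
    n = len(records)
    counts = {k: 0 for k in range(5)}
    for r in records:
        counts[min(r.n_coloc, 4)] += 1
    pct = {
        t: 100.0 * sum(c for k, c in counts.items() if k >= t) / n
        for t in PCT_THRESHOLDS
    }
    genotype, paint = conditions.pop()
    return ColocalizationSummary(genotype, paint, n, counts, pct)


def _cells_at_least(summary: ColocalizationSummary, threshold: int) -> int:
    return sum(c for k, c in summary.counts_by_k.items() if k >= threshold)


def fisher_pairwise(
    summary_a: ColocalizationSummary,
    summary_b: ColocalizationSummary,
    threshold: int,
    sided: str = "two",
) -> float:
    """Fisher's exact p for the 2x2 table [k >= threshold vs k < threshold]
    by [condition a vs condition b].

    ``sided="two"`` is the default; ``sided="one-greater"`` tests for
    greater co-localization in condition a.
    """
    if not 1 <= threshold <= 4:
        raise ValueError("threshold must lie in 1..4")
    if summary_a.n_cells < 1 or summary_b.n_cells < 1:
        raise ValueError("both conditions need at least one cell")
    if sided not in ("two", "one-greater"):
        raise ValueError("sided must be 'two' or 'one-greater'")
    a_ge = _cells_at_least(summary_a, threshold)
    b_ge = _cells_at_least(summary_b, threshold)
    table = [
        [a_ge, summary_a.n_cells - a_ge],
        [b_ge, summary_b.n_cells - b_ge],
    ]
    alternative = "two-sided" if sided == "two" else "greater"
    return float(fisher_exact(table, alternative=alternative).pvalue)


def call_linkage(
    tg_summaries: dict[str, ColocalizationSummary],
    reference: ColocalizationSummary,
    alpha: float = 0.05,
    threshold: int = 2,
) -> dict[str, LinkageCall]:
    """Call genetic linkage of the transgene per candidate chromosome.

    A chromosome is linked when its TG "k >= threshold" frequency is
    (a) not significantly below the positive-control reference (Xic and
    its own chromosome) and (b) significantly above every other
    candidate autosome (one-sided Fisher).  Degenerate reference sizes
    give no call; identical conditions everywhere are reported linked
    with a warning.
    """
    calls: dict[str, LinkageCall] = {}
    ref_pct = reference.pct_at_least[threshold]
    for chrom, summary in tg_summaries.items():
        warns: list[str] = []
        if reference.n_cells < 2:
            calls[chrom] = LinkageCall(
                chrom,
                False,
                float("nan"),
                {},
                ["reference condition has < 2 cells: no call possible"],
            )
            continue
        p_ref = fisher_pairwise(summary, reference, threshold, sided="two")
        below_ref = p_ref < alpha and summary.pct_at_least[threshold] < ref_pct
        p_controls: dict[str, float] = {}
        above_all = True
        for other, other_summary in tg_summaries.items():
            if other == chrom:
                continue
            p = fisher_pairwise(summary, other_summary, threshold, sided="one-greater")
            p_controls[other] = p
            if p >= alpha:
                above_all = False
        if not p_controls:
            warns.append("no control autosomes supplied")
        identical = all(
            _cells_at_least(s, threshold) == _cells_at_least(summary, threshold)
            and s.n_cells == summary.n_cells
            for s in tg_summaries.values()
        ) and _cells_at_least(summary, threshold) / summary.n_cells == ref_pct / 100.0
        if identical and not below_ref:
            warns.append(
                "all conditions indistinguishable from the reference: "
                "linkage call is degenerate"
            )
            linked = True
        else:
            linked = (not below_ref) and above_all
        calls[chrom] = LinkageCall(chrom, linked, p_ref, p_controls, warns)
    return calls
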