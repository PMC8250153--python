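"""3D nuclear distance statistic between segment probes and Xic spots.

For every eligible nucleus the two shortest straight-line (centre to
centre) distances between segment-probe spots and Xic spots are
recorded and averaged; TG per-cell averages are normalized by
subtracting the median of the WT per-cell averages for the same segment
probe, which removes the baseline contribution of transient contacts
with the endogenous Xic.  Normalized distances are compared between
segments with Welch's two-sample t-test, and segments are ranked by
median normalized distance to nominate the probe nearest the transgene
integration site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import ttest_ind

from .simulate import SEGMENT, XIC, Nucleus


@dataclass
class DistanceRecord:
    """Per-cell two-shortest-distance measurement for one segment probe."""

    cell_id: str
    genotype: str
    segment_id: str
    d1: float
    d2: float
    cell_avg: float
    normalized: float | None = None  # TG only, filled by normalize_tg


@dataclass
class SegmentComparison:
    segment_id: str
    reference_segment_id: str
    n_segment: int
    n_reference: int
    t_statistic: float
    p_value: float
    degenerate: bool = False


def pairwise_distances(nucleus: Nucleus, segment_id: str) -> np.ndarray:
    """Euclidean 3D distance matrix, segment spots (rows) x Xic spots
    (columns), for one segment probe in one nucleus."""
    seg = nucleus.spots_in_channel(SEGMENT, target=segment_id)
    xic = nucleus.spots_in_channel(XIC)
    if not seg:
        raise ValueError(
            f"nucleus {nucleus.cell_id} has no spots for segment {segment_id!r}"
        )
    if not xic:
        raise ValueError(f"nucleus {nucleus.cell_id} has no Xic spots")
    return cdist(
        np.array([s.xyz for s in seg]), np.array([s.xyz for s in xic])
    )


def two_shortest_average(
    matrix: np.ndarray, require_distinct: bool = True
) -> tuple[float, float, float] | None:
    """Select the two shortest distances and their per-cell average.

    With ``require_distinct`` (default) the two measurements must use
    distinct segment and distinct Xic spots: the global minimum pair is
    taken first, both spots are removed, and the minimum of the
    remaining sub-matrix is taken second (greedy selection, one
    measurement per transgene copy).  Without it the two smallest matrix
    entries are used regardless of shared spots.  Returns ``None`` when
    fewer than two eligible pairs exist — the cell is excluded, not an
    error.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        return None
    if require_distinct:
        if m.shape[0] < 2 or m.shape[1] < 2:
            return None
        i, j = np.unravel_index(np.argmin(m), m.shape)
        d1 = float(m[i, j])
        rest = np.delete(np.delete(m, i, axis=0), j, axis=1)
        d2 = float(rest.min())
    else:
        if m.size < 2:
            return None
        flat = np.sort(m, axis=None)
        d1, d2 = float(flat[0]), float(flat[1])
    if d2 < d1:  # greedy second pick can only be >= the global minimum
        d1, d2 = d2, d1
    return d1, d2, (d1 + d2) / 2.0


def collect_distance_records(
    nuclei: list[Nucleus],
    segment_id: str,
    require_distinct: bool = True,
) -> tuple[list[DistanceRecord], int]:
    """Two-shortest-average records for every eligible nucleus.

    Returns ``(records, n_excluded)``; nuclei without two eligible
    spot pairs (unresolvable or merged signals) are counted, not kept.
    """
    records: list[DistanceRecord] = []
    n_excluded = 0
    for nuc in nuclei:
        try:
            matrix = pairwise_distances(nuc, segment_id)
        except ValueError:
            n_excluded += 1
            continue
        picked = two_shortest_average(matrix, require_distinct=require_distinct)
        if picked is None:
            n_excluded += 1
            continue
        d1, d2, avg = picked
        records.append(DistanceRecord(nuc.cell_id, nuc.genotype, segment_id, d1, d2, avg))
    return records, n_excluded


def normalize_tg(
    tg_cell_avgs: "np.ndarray | list[float]",
    wt_cell_avgs: "np.ndarray | list[float]",
) -> np.ndarray:
    """Normalized TG distances: each TG per-cell average minus the
    median of the WT per-cell averages for the same segment probe.
    Negative values (TG closer than the WT baseline) are meaningful and
    retained."""
    wt = np.asarray(wt_cell_avgs, dtype=float)
    if wt.size == 0:
        raise ValueError("normalization needs at least one WT cell")
    return np.asarray(tg_cell_avgs, dtype=float) - float(np.median(wt))


def normalize_records(
    tg_records: list[DistanceRecord], wt_records: list[DistanceRecord]
) -> list[DistanceRecord]:
    """Fill the ``normalized`` field of TG records in place (per segment)."""
    segments = {r.segment_id for r in tg_records}
    for seg in segments:
        wt = [r.cell_avg for r in wt_records if r.segment_id == seg]
        tg = [r for r in tg_records if r.segment_id == seg]
        values = normalize_tg([r.cell_avg for r in tg], wt)
        for r, v in zip(tg, values):
            r.normalized = float(v)
    return tg_records


def compare_segments(
    normalized_by_segment: dict[str, "np.ndarray | list[float]"],
    reference: str,
) -> list[SegmentComparison]:
    """Welch two-sample t-test of each segment's normalized distances
    against the reference segment (two-sided)."""
    if reference not in normalized_by_segment:
        raise ValueError(f"reference segment {reference!r} not present")
    ref = np.asarray(normalized_by_segment[reference], dtype=float)
    if ref.size < 2:
        raise ValueError("reference segment needs at least two cells")
    out: list[SegmentComparison] = []
    for seg in sorted(normalized_by_segment):
        if seg == reference:
            continue
        vals = np.asarray(normalized_by_segment[seg], dtype=float)
        if vals.size < 2:
            raise ValueError(f"segment {seg!r} needs at least two cells")
        degenerate = False
        if np.var(vals) == 0 and np.var(ref) == 0:
            if float(np.mean(vals)) == float(np.mean(ref)):
                t, p = 0.0, 1.0
            else:
                t, p = math.inf, 0.0
            degenerate = True
            warnings.warn(
                f"zero variance comparing {seg!r} to {reference!r}: "
                "p-value is degenerate",
                stacklevel=2,
            )
        else:
            res = ttest_ind(vals, ref, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            if math.isnan(p):
                degenerate = True
                warnings.warn(
                    f"degenerate t-test for {seg!r} vs {reference!r}", stacklevel=2
                )
        out.append(
            SegmentComparison(seg, reference, int(vals.size), int(ref.size), t, p, degenerate)
        )
    return out


def plot_normalized_distances(
    normalized_by_segment: dict[str, "np.ndarray | list[float]"],
    path: str,
) -> None:
    """Boxplot of normalized distances per segment probe, saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    segments = sorted(normalized_by_segment)
    data = [np.asarray(normalized_by_segment[s], dtype=float) for s in segments]
    fig, ax = plt.subplots(figsize=(1.2 * len(segments) + 1.5, 4))
    ax.boxplot(data, tick_labels=segments)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("segment probe")
    ax.set_ylabel("normalized distance to Xic (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rank_candidate_insertion_site(
    normalized_by_segment: dict[str, "np.ndarray | list[float]"],
) -> list[tuple[str, float, bool]]:
    """Segments ordered by ascending median normalized distance.

    The top segment is the candidate nearest the transgene integration
    site.  Returns ``(segment_id, median, tied)`` triples; exact median
    ties are ordered by segment id and flagged.
    """
    if len(normalized_by_segment) < 2:
        raise ValueError("ranking needs at least two segments")
    medians = {
        seg: float(np.median(np.asarray(v, dtype=float)))
        for seg, v in normalized_by_segment.items()
    }
    ordered = sorted(medians, key=lambda s: (medians[s], s))
    counts: dict[float, int] = {}
    for m in medians.values():
        counts[m] = counts.get(m, 0) + 1
    return [(s, medians[s], counts[medians[s]] > 1) for s in ordered]
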