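"""Synthetic data generators for the transgene-silencing pipeline.

Two generators stand in for the study's raw data:

``generate_de_table``
    Emits a differential-expression table (one row per gene: coordinates,
    log2 fold-change TG vs WT, BH-adjusted p, group-mean FPKMs) with
    silenced gene clusters planted at known positions on a target
    chromosome, plus a ground-truth sidecar marking the planted genes.
    Adjusted p-values are generated directly (Beta-concentrated near 0
    for planted genes, Uniform(0, 1) for the background); the DE test
    itself is upstream of this pipeline.

``generate_nuclei``
    Emits per-cell 3D FISH observations for wildtype (WT) and transgenic
    (TG) tetraploid male fibroblasts: spherical chromosome territories
    inside a spherical nucleus, endogenous Xic spots inside the two X
    territories, two transgenic Xic spots inside two target-chromosome
    territories when the transgene is linked, segment probe spots in
    every target-chromosome territory, transient territory–Xic contacts,
    Gaussian localization noise, and merging of unresolvably close spots.

Within a transgene-carrying territory the spatial distance between the
transgene spot and a segment spot follows a polymer-like power law,
``prefactor * (genomic separation)^exponent`` in expectation, so nearer
genomic neighbours of the integration site are nearer in space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

XIC = "XIC"
SEGMENT = "SEGMENT"
PAINT = "PAINT"

DE_COLUMNS = ["gene_id", "chrom", "start", "end", "log2fc", "adj_p", "fpkm_wt", "fpkm_tg"]


@dataclass
class Spot:
    """One FISH pinpoint signal (coordinates in µm, nucleus-centred)."""

    cell_id: str
    channel: str  # XIC or SEGMENT
    chromosome_copy: str  # "chrom:copy" or "unknown" after merging
    x: float
    y: float
    z: float
    target: str = ""  # segment id, or endogenous/transgene for XIC spots

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Territory:
    """One chromosome-paint territory, modelled as a sphere."""

    chrom: str
    copy: int
    center: np.ndarray
    radius: float


@dataclass
class Nucleus:
    """One cell's FISH observation: spots plus territory descriptors."""

    cell_id: str
    genotype: str  # WT or TG
    nucleus_radius: float
    spots: list[Spot] = field(default_factory=list)
    territories: list[Territory] = field(default_factory=list)

    def spots_in_channel(self, channel: str, target: str | None = None) -> list[Spot]:
        out = [s for s in self.spots if s.channel == channel]
        if target is not None:
            out = [s for s in out if s.target == target]
        return out

    def territories_of(self, chrom: str) -> list[Territory]:
        return [t for t in self.territories if t.chrom == chrom]


# ---------------------------------------------------------------------------
# DE table generation
# ---------------------------------------------------------------------------

def generate_de_table(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a DE result table with planted silenced clusters.

    Returns ``(table, truth)``: the table has the canonical DE columns,
    the truth sidecar has ``gene_id``, ``planted`` and ``cluster``
    (planted-cluster index, -1 for background genes).  Identical configs
    and seeds give byte-identical tables.
    """
    target_len = config.chromosome_lengths[config.target_chromosome]
    if config.cluster_width > target_len:
        raise ValueError(
            f"cluster_width {config.cluster_width} exceeds length of "
            f"chromosome {config.target_chromosome} ({target_len} bp)"
        )
    n_planted = config.n_silenced_clusters * config.genes_per_cluster
    if n_planted > config.n_genes_per_chromosome:
        raise ValueError("more planted genes than genes per chromosome")

    rng = np.random.default_rng(config.seed)
    max_gene_len = 100_000

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for chrom in sorted(config.karyotype, key=_chrom_sort_key):
        length = config.chromosome_lengths[chrom]
        n = config.n_genes_per_chromosome
        planted_mask = np.zeros(n, dtype=bool)
        cluster_idx = np.full(n, -1)
        if chrom == config.target_chromosome and n_planted > 0:
            anchors = _cluster_anchors(rng, length, config)
            starts = np.empty(n, dtype=np.int64)
            k = 0
            for ci, anchor in enumerate(anchors):
                lo, hi = anchor, anchor + config.cluster_width
                s = np.sort(rng.integers(lo, hi - max_gene_len, config.genes_per_cluster))
                starts[k : k + config.genes_per_cluster] = s
                planted_mask[k : k + config.genes_per_cluster] = True
                cluster_idx[k : k + config.genes_per_cluster] = ci
                k += config.genes_per_cluster
            starts[k:] = rng.integers(1, length - max_gene_len, n - k)
            order = np.argsort(starts, kind="stable")
            starts = starts[order]
            planted_mask = planted_mask[order]
            cluster_idx = cluster_idx[order]
        else:
            starts = np.sort(rng.integers(1, length - max_gene_len, n))
        gene_lens = rng.integers(1_000, max_gene_len, n)
        ends = starts + gene_lens

        log2fc = rng.normal(0.0, config.background_log2fc_sd, n)
        adj_p = rng.uniform(0.0, 1.0, n)
        n_pl = int(planted_mask.sum())
        if n_pl:
            log2fc[planted_mask] = rng.normal(
                config.silencing_log2fc_mean, config.silencing_log2fc_sd, n_pl
            )
            adj_p[planted_mask] = rng.beta(0.5, 500.0, n_pl)
        fpkm_wt = np.exp(
            rng.normal(config.baseline_fpkm_log_mean, config.baseline_fpkm_log_sd, n)
        )
        fpkm_tg = fpkm_wt * np.exp2(log2fc)

        for i in range(n):
            gid = f"gene_{chrom}_{i:04d}"
            rows.append(
                {
                    "gene_id": gid,
                    "chrom": chrom,
                    "start": int(starts[i]),
                    "end": int(ends[i]),
                    "log2fc": round(float(log2fc[i]), 6),
                    "adj_p": round(float(adj_p[i]), 8),
                    "fpkm_wt": round(float(fpkm_wt[i]), 6),
                    "fpkm_tg": round(float(fpkm_tg[i]), 6),
                }
            )
            truth_rows.append(
                {"gene_id": gid, "planted": bool(planted_mask[i]), "cluster": int(cluster_idx[i])}
            )

    table = pd.DataFrame(rows, columns=DE_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "planted", "cluster"])
    return table, truth


def _cluster_anchors(
    rng: np.random.Generator, chrom_len: int, config: SimulationConfig
) -> list[int]:
    """Non-overlapping cluster start positions, >=10 Mb apart so planted
    clusters stay distinct under the 5 Mb linkage window."""
    min_sep = config.cluster_width + 10_000_000
    span = chrom_len - config.cluster_width - 1
    for _ in range(1000):
        anchors = np.sort(rng.integers(1, span, config.n_silenced_clusters))
        if config.n_silenced_clusters == 1 or np.all(np.diff(anchors) >= min_sep):
            return [int(a) for a in anchors]
    raise ValueError(
        "could not place non-overlapping silenced clusters; "
        "reduce n_silenced_clusters or cluster_width"
    )


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


# ---------------------------------------------------------------------------
# Nucleus generation
# ---------------------------------------------------------------------------

def _uniform_in_ball(rng: np.random.Generator, radius: float, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * r


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_nuclei(
    config: SimulationConfig, linked: bool = True
) -> dict[str, list[Nucleus]]:
    """Simulate FISH observations for WT and TG cells.

    ``linked=True`` integrates the two transgene copies inside two
    target-chromosome territories of each TG cell (the study geometry);
    ``linked=False`` scatters the transgenic Xic spots uniformly in the
    nucleus, the null model for calibration.  Returns a dict keyed by
    genotype.
    """
    if linked and config.target_chromosome in ("X", "Y"):
        raise ValueError("a linked transgene must be autosomal, not on X or Y")
    rng = np.random.default_rng(config.seed)
    out: dict[str, list[Nucleus]] = {}
    for genotype in ("WT", "TG"):
        cells = []
        for i in range(config.n_cells_per_genotype):
            cells.append(
                _generate_cell(rng, config, genotype, linked, f"{genotype}_{i:04d}")
            )
        out[genotype] = cells
    return out


def _generate_cell(
    rng: np.random.Generator,
    config: SimulationConfig,
    genotype: str,
    linked: bool,
    cell_id: str,
) -> Nucleus:
    rn, rt = config.nucleus_radius, config.territory_radius
    center_radius = rn - rt  # territories fully inside the nucleus

    territories: list[Territory] = []
    for chrom in sorted(config.karyotype, key=_chrom_sort_key):
        centers = _uniform_in_ball(rng, center_radius, config.karyotype[chrom])
        for copy, c in enumerate(centers):
            territories.append(Territory(chrom, copy, c, rt))

    spots: list[Spot] = []

    # Endogenous Xic: one spot inside each X territory.
    x_territories = [t for t in territories if t.chrom == "X"]
    for t in x_territories:
        p = t.center + _uniform_in_ball(rng, rt)[0]
        spots.append(Spot(cell_id, XIC, f"X:{t.copy}", *p, target="endogenous"))

    # Transgenic Xic: two copies at one autosomal site (TG only).
    tg_territories: list[Territory] = []
    transgene_pos: dict[int, np.ndarray] = {}
    if genotype == "TG":
        if linked:
            candidates = [t for t in territories if t.chrom == config.target_chromosome]
            picked = rng.choice(len(candidates), size=2, replace=False)
            tg_territories = [candidates[j] for j in sorted(picked)]
            for t in tg_territories:
                # anchored near the territory centre so power-law segment
                # placement stays inside the sphere
                p = t.center + _uniform_in_ball(rng, 0.3 * rt)[0]
                transgene_pos[id(t)] = p
                spots.append(
                    Spot(cell_id, XIC, f"{t.chrom}:{t.copy}", *p, target="transgene")
                )
        else:
            for p in _uniform_in_ball(rng, rn, 2):
                spots.append(Spot(cell_id, XIC, "unknown", *p, target="transgene"))

    # Transient contacts: an unlinked territory relocates next to an Xic
    # spot so the spot falls just inside it.
    xic_positions = np.array([s.xyz for s in spots])
    linked_ids = {id(t) for t in tg_territories} | {id(t) for t in x_territories}
    if config.contact_probability > 0 and len(xic_positions):
        for t in territories:
            if id(t) in linked_ids:
                continue
            if rng.uniform() < config.contact_probability:
                target_spot = xic_positions[rng.integers(len(xic_positions))]
                center = target_spot + 0.9 * rt * _unit_vector(rng)
                norm = np.linalg.norm(center)
                if norm > center_radius:  # keep the territory inside the nucleus
                    center = center * (center_radius / norm)
                t.center = center

    # Segment probe spots in every target-chromosome territory.
    for t in territories:
        if t.chrom != config.target_chromosome:
            continue
        anchor = transgene_pos.get(id(t))
        for seg, pos in sorted(config.segment_positions.items()):
            if anchor is not None:
                sep = abs(pos - config.transgene_genomic_position)
                p = _place_scaled(rng, anchor, t, sep, config)
            else:
                p = t.center + _uniform_in_ball(rng, rt)[0]
            spots.append(Spot(cell_id, SEGMENT, f"{t.chrom}:{t.copy}", *p, target=seg))

    # Localization noise, containment, resolvability merging.
    if config.localization_noise_sd > 0:
        for s in spots:
            p = s.xyz + rng.normal(0.0, config.localization_noise_sd, 3)
            norm = np.linalg.norm(p)
            if norm > rn:
                p = p * (rn / norm)
            s.x, s.y, s.z = p
    spots = _merge_unresolvable(spots, config.resolvability_threshold)

    return Nucleus(cell_id, genotype, rn, spots, territories)


def _place_scaled(
    rng: np.random.Generator,
    anchor: np.ndarray,
    territory: Territory,
    genomic_sep: int,
    config: SimulationConfig,
) -> np.ndarray:
    """Place a segment spot at power-law spatial distance from the
    transgene anchor, inside the territory sphere (rejection sampling)."""
    mean_d = config.scaling_prefactor * float(genomic_sep) ** config.scaling_exponent
    for _ in range(50):
        d = mean_d * rng.gamma(4.0, 0.25)
        for _ in range(100):
            p = anchor + d * _unit_vector(rng)
            if np.linalg.norm(p - territory.center) <= territory.radius:
                return p
    # distance unreachable inside the sphere: pull toward the centre
    u = territory.center - anchor
    un = np.linalg.norm(u)
    direction = u / un if un > 0 else _unit_vector(rng)
    d = min(mean_d, un + territory.radius * 0.99)
    return anchor + d * direction


def _merge_unresolvable(spots: list[Spot], threshold: float) -> list[Spot]:
    """Merge same-channel spots closer than the resolvability threshold
    into their centroid (union-find over the < threshold graph)."""
    if threshold <= 0 or len(spots) < 2:
        return spots
    out: list[Spot] = []
    # Each segment probe is a separate hybridization, so segment spots
    # only compete for resolution with spots of the same probe; all Xic
    # spots share one probe.
    keys: list[tuple[str, str | None]] = [(XIC, None), (PAINT, None)]
    keys += [(SEGMENT, t) for t in sorted({s.target for s in spots if s.channel == SEGMENT})]
    for channel, target in keys:
        group = [
            s
            for s in spots
            if s.channel == channel and (target is None or s.target == target)
        ]
        if len(group) < 2:
            out.extend(group)
            continue
        pos = np.array([s.xyz for s in group])
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if np.linalg.norm(pos[i] - pos[j]) < threshold:
                    parent[find(i)] = find(j)
        comps: dict[int, list[int]] = {}
        for i in range(len(group)):
            comps.setdefault(find(i), []).append(i)
        for members in comps.values():
            if len(members) == 1:
                out.append(group[members[0]])
            else:
                centroid = pos[members].mean(axis=0)
                copies = {group[i].chromosome_copy for i in members}
                targets = {group[i].target for i in members}
                out.append(
                    Spot(
                        group[members[0]].cell_id,
                        channel,
                        copies.pop() if len(copies) == 1 else "unknown",
                        *centroid,
                        target=targets.pop() if len(targets) == 1 else "merged",
                    )
                )
    return out
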