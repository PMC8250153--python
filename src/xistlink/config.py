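"""Simulation and pipeline configuration objects.

``SimulationConfig`` encodes the study conditions the synthetic data
emulates: tetraploid male fibroblast karyotype, a two-copy Xic transgene
integrated at one autosomal site on chromosome 1, chromosome territories
as spheres inside a spherical nucleus, a power-law relation between
genomic separation and intra-territory spatial distance, transient
territory–Xic contacts, FISH localization noise, and DE tables with
silenced gene clusters planted on the target chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from .genome import CHROM_LENGTHS_BP, TETRAPLOID_MALE_KARYOTYPE, normalize_chrom


def _default_segments() -> dict[str, int]:
    # Two probe pairs mirroring the study layout on Chr 1: B/E in the
    # proximal silenced cluster (~73 Mb), A/C in the distal cluster
    # (~136 Mb) that hosts the integration site.  Separations from the
    # transgene: A 0.25 Mb, C 0.5 Mb, E ~61.7 Mb, B ~62.5 Mb.
    return {
        "A": 135_750_000,
        "B": 73_000_000,
        "C": 136_000_000,
        "E": 73_800_000,
    }


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic DE and nucleus generators.

    Lengths are µm (spatial) or bp (genomic); log2 fold-changes are
    dimensionless; FPKM baselines are on the natural-log scale.
    """

    seed: int = 0
    n_cells_per_genotype: int = 100
    nucleus_radius: float = 5.0
    territory_radius: float = 1.0
    karyotype: dict[str, int] = field(
        default_factory=lambda: dict(TETRAPLOID_MALE_KARYOTYPE)
    )
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(CHROM_LENGTHS_BP)
    )
    target_chromosome: str = "1"
    transgene_genomic_position: int = 135_500_000
    segment_positions: dict[str, int] = field(default_factory=_default_segments)
    scaling_exponent: float = 1.0 / 3.0
    scaling_prefactor: float = 0.002
    contact_probability: float = 0.02
    localization_noise_sd: float = 0.05
    resolvability_threshold: float = 0.3
    n_genes_per_chromosome: int = 100
    n_silenced_clusters: int = 2
    genes_per_cluster: int = 4
    cluster_width: int = 1_500_000
    silencing_log2fc_mean: float = -2.5
    silencing_log2fc_sd: float = 0.8
    background_log2fc_sd: float = 0.3
    baseline_fpkm_log_mean: float = 2.0
    baseline_fpkm_log_sd: float = 1.0

    def __post_init__(self) -> None:
        self.target_chromosome = normalize_chrom(self.target_chromosome)
        self.karyotype = {normalize_chrom(c): int(n) for c, n in self.karyotype.items()}
        self.chromosome_lengths = {
            normalize_chrom(c): int(length)
            for c, length in self.chromosome_lengths.items()
        }
        self.validate()

    def validate(self) -> None:
        positive = {
            "nucleus_radius": self.nucleus_radius,
            "territory_radius": self.territory_radius,
            "n_cells_per_genotype": self.n_cells_per_genotype,
            "n_genes_per_chromosome": self.n_genes_per_chromosome,
            "genes_per_cluster": self.genes_per_cluster,
            "cluster_width": self.cluster_width,
            "scaling_prefactor": self.scaling_prefactor,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name, value in (
            ("contact_probability", self.contact_probability),
            ("localization_noise_sd", self.localization_noise_sd),
            ("resolvability_threshold", self.resolvability_threshold),
            ("n_silenced_clusters", self.n_silenced_clusters),
        ):
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if not 0.0 <= self.contact_probability <= 1.0:
            raise ValueError("contact_probability must lie in [0, 1]")
        if self.territory_radius >= self.nucleus_radius:
            raise ValueError("territory_radius must be smaller than nucleus_radius")
        if self.silencing_log2fc_mean > -1.0:
            raise ValueError(
                "silencing_log2fc_mean must be <= -1 (planted genes are silenced)"
            )
        target_len = self.chromosome_lengths.get(self.target_chromosome)
        if target_len is None:
            raise ValueError(
                f"no chromosome length for target chromosome {self.target_chromosome!r}"
            )
        if not 1 <= self.transgene_genomic_position <= target_len:
            raise ValueError("transgene_genomic_position outside target chromosome")
        for seg, pos in self.segment_positions.items():
            if not 1 <= pos <= target_len:
                raise ValueError(
                    f"segment {seg!r} position {pos} outside target chromosome"
                )
        for chrom in self.karyotype:
            if chrom not in self.chromosome_lengths:
                raise ValueError(f"karyotype chromosome {chrom!r} has no length")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """Paths, thresholds and bookkeeping for the end-to-end pipeline."""

    de_table: str | Path | None = None
    spots: str | Path | None = None
    territories: str | Path | None = None
    p_cutoff: float = 0.01
    lfc_cutoff: float = 1.0
    window_bp: int = 5_000_000
    coloc_threshold: int = 2
    margin_um: float = 0.0
    alpha: float = 0.05
    paint_chromosomes: tuple[str, ...] = ("1", "4", "9")
    reference_paint: str = "X"
    segments: tuple[str, ...] = ("A", "B", "C", "E")
    reference_segment: str = "A"
    min_clustered: int = 4
    seed: int = 0
    out_dir: str | Path | None = None
    de_only: bool = False

    def __post_init__(self) -> None:
        if self.p_cutoff <= 0 or self.lfc_cutoff <= 0:
            raise ValueError("p_cutoff and lfc_cutoff must be positive")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 1 <= self.coloc_threshold <= 4:
            raise ValueError("coloc_threshold must lie in 1..4")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.paint_chromosomes = tuple(
            normalize_chrom(c) for c in self.paint_chromosomes
        )
        self.reference_paint = normalize_chrom(self.reference_paint)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("paint_chromosomes", "segments"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
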