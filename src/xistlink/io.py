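"""Readers and writers for the pipeline's plain-text formats.

DE tables are TSV/CSV with columns ``gene_id, chrom, start, end,
log2fc, adj_p, fpkm_wt, fpkm_tg``.  Genomic coordinates are held
1-based inclusive internally and parsed permissively — thousands
separators and stray spaces ("72, 824, 480") are stripped, matching the
formatting conventions of published coordinate strings.  Cluster spans
are exported as BED (0-based half-open, converted on write).  Spot and
territory tables are CSV with spatial coordinates in µm.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import is_known_chrom, normalize_chrom
from .profile import GeneCluster
from .simulate import DE_COLUMNS, Nucleus, Spot, Territory

SPOT_COLUMNS = ["cell_id", "genotype", "channel", "x_um", "y_um", "z_um", "target"]
TERRITORY_COLUMNS = ["cell_id", "chromosome", "copy", "cx_um", "cy_um", "cz_um", "radius_um"]

_NUMERIC_DE_FIELDS = {
    "start": int,
    "end": int,
    "log2fc": float,
    "adj_p": float,
    "fpkm_wt": float,
    "fpkm_tg": float,
}


def parse_genomic_coordinate(text: object) -> int:
    """Parse a genomic coordinate, tolerating ``72, 824, 480`` style
    thousands separators and surrounding whitespace."""
    s = str(text).replace(",", "").replace(" ", "")
    return int(s)


def _parse_numeric(value: object, caster):
    s = str(value).strip()
    if caster is int:
        return parse_genomic_coordinate(s)
    return float(s.replace(",", ""))


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE result table from TSV or CSV into typed records.

    Malformed numeric fields raise with the 1-based line number of the
    offending row; unknown chromosome labels are retained with a
    warning.  A header-only file yields an empty table.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)
    missing = [c for c in DE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"DE table is missing required column {missing[0]!r}")
    rows = []
    for idx, row in raw.iterrows():
        line_no = int(idx) + 2  # header is line 1
        rec = {"gene_id": str(row["gene_id"]).strip()}
        chrom = normalize_chrom(row["chrom"])
        if not is_known_chrom(chrom):
            warnings.warn(
                f"line {line_no}: unknown chromosome label {row['chrom']!r}; "
                "row retained",
                stacklevel=2,
            )
        rec["chrom"] = chrom
        for col, caster in _NUMERIC_DE_FIELDS.items():
            try:
                rec[col] = _parse_numeric(row[col], caster)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"line {line_no}: malformed value {row[col]!r} in column {col!r}"
                ) from exc
        rows.append(rec)
    table = pd.DataFrame(rows, columns=DE_COLUMNS)
    if not rows:
        table = table.astype(
            {"start": int, "end": int, "log2fc": float, "adj_p": float,
             "fpkm_wt": float, "fpkm_tg": float},
            errors="ignore",
        )
    return table


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_truth_labels(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED export of cluster spans
# ---------------------------------------------------------------------------

def write_bed(clusters: list[GeneCluster], path: str | Path) -> None:
    """Write cluster spans as BED3+name.

    Internal spans are 1-based inclusive; BED is 0-based half-open, so
    a span [s, e] becomes ``s-1, e``.  Chromosome labels gain a ``chr``
    prefix on export.  An empty cluster list yields a track header only.
    """
    with open(path, "w", newline="") as fh:
        fh.write('track name=silenced_clusters description="down-regulated gene clusters"\n')
        for i, c in enumerate(clusters, start=1):
            fh.write(f"chr{c.chrom}\t{c.span_start - 1}\t{c.span_end}\tcluster_{i}\n")


def read_bed(path: str | Path) -> list[GeneCluster]:
    """Read BED cluster spans back to the internal 1-based inclusive
    convention (round-trip inverse of :func:`write_bed`; member gene
    lists are not stored in BED and come back empty)."""
    clusters: list[GeneCluster] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            chrom = normalize_chrom(fields[0])
            start0, end = int(fields[1]), int(fields[2])
            clusters.append(GeneCluster(chrom, [], start0 + 1, end))
    return clusters


# ---------------------------------------------------------------------------
# Spot / territory CSVs
# ---------------------------------------------------------------------------

def write_spot_table(nuclei: list[Nucleus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SPOT_COLUMNS)
        for nuc in nuclei:
            for s in nuc.spots:
                writer.writerow(
                    [nuc.cell_id, nuc.genotype, s.channel,
                     f"{s.x:.6f}", f"{s.y:.6f}", f"{s.z:.6f}", s.target]
                )


def write_territory_table(nuclei: list[Nucleus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TERRITORY_COLUMNS)
        for nuc in nuclei:
            for t in nuc.territories:
                writer.writerow(
                    [nuc.cell_id, t.chrom, t.copy,
                     f"{t.center[0]:.6f}", f"{t.center[1]:.6f}",
                     f"{t.center[2]:.6f}", f"{t.radius:.6f}"]
                )


def read_nuclei(
    spot_path: str | Path,
    territory_path: str | Path | None = None,
    nucleus_radius: float = 5.0,
) -> list[Nucleus]:
    """Rebuild per-cell observations from spot (and optionally
    territory) CSVs.  The ``target`` column is optional for tables that
    carry only Xic or paint spots."""
    spots = pd.read_csv(spot_path, dtype={"cell_id": str})
    for col in ("cell_id", "genotype", "channel", "x_um", "y_um", "z_um"):
        if col not in spots.columns:
            raise ValueError(f"spot table is missing required column {col!r}")
    if "target" not in spots.columns:
        spots["target"] = ""
    spots["target"] = spots["target"].fillna("")

    nuclei: dict[str, Nucleus] = {}
    for row in spots.itertuples(index=False):
        cid = str(row.cell_id)
        nuc = nuclei.get(cid)
        if nuc is None:
            nuc = Nucleus(cid, str(row.genotype), nucleus_radius)
            nuclei[cid] = nuc
        nuc.spots.append(
            Spot(cid, str(row.channel), "unknown",
                 float(row.x_um), float(row.y_um), float(row.z_um),
                 target=str(row.target))
        )
    if territory_path is not None:
        terr = pd.read_csv(territory_path, dtype={"cell_id": str})
        for col in TERRITORY_COLUMNS:
            if col not in terr.columns:
                raise ValueError(f"territory table is missing required column {col!r}")
        for row in terr.itertuples(index=False):
            cid = str(row.cell_id)
            if cid not in nuclei:
                continue
            nuclei[cid].territories.append(
                Territory(
                    normalize_chrom(row.chromosome),
                    int(row.copy),
                    np.array([float(row.cx_um), float(row.cy_um), float(row.cz_um)]),
                    float(row.radius_um),
                )
            )
    return list(nuclei.values())
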