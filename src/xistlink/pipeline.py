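"""End-to-end pipeline: DE silencing profile -> co-localization linkage
-> 3D distance ranking of the candidate integration site.

The stages mirror the order of the underlying study: the DE table
nominates candidate silenced chromosomes; dual-color FISH
co-localization calls the genetically linked chromosome; the
two-shortest-distance statistic ranks segment probes by spatial
proximity to the transgene.  The summary bundle is machine-readable
JSON plus TSV reports, and every excluded nucleus is logged with its
reason so the scoring-eligibility rule cannot silently bias results.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import coloc as coloc_mod
from . import distance as dist_mod
from . import io as io_mod
from . import profile as profile_mod
from .config import PipelineConfig
from .simulate import Nucleus


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


@_stage("silencing_profile")
def _run_profile(config: PipelineConfig, out_dir: Path | None) -> dict:
    table = io_mod.read_de_table(config.de_table)
    report = profile_mod.profile_de_table(
        table,
        p_cutoff=config.p_cutoff,
        lfc_cutoff=config.lfc_cutoff,
        window=config.window_bp,
        min_clustered=config.min_clustered,
    )
    if out_dir is not None:
        io_mod.write_bed(report["clusters"], out_dir / "clusters.bed")
        report["ranking"].to_csv(out_dir / "chromosome_ranking.tsv", sep="\t", index=False)
        report["summaries"].to_csv(out_dir / "chromosome_summaries.tsv", sep="\t", index=False)
    return report


@_stage("colocalization")
def _run_coloc(config: PipelineConfig, nuclei: list[Nucleus], out_dir: Path | None) -> dict:
    tg = [n for n in nuclei if n.genotype == "TG"]
    wt = [n for n in nuclei if n.genotype == "WT"]
    if not tg:
        raise ValueError("no TG cells in the spot table")
    paints = list(config.paint_chromosomes)
    records: list[coloc_mod.CellColocRecord] = []
    tg_summaries: dict[str, coloc_mod.ColocalizationSummary] = {}
    wt_summaries: dict[str, coloc_mod.ColocalizationSummary] = {}
    for paint in paints + [config.reference_paint]:
        tg_recs = [coloc_mod.score_cell(n, paint, config.margin_um) for n in tg]
        records.extend(tg_recs)
        tg_summaries[paint] = coloc_mod.summarize_condition(tg_recs)
        if wt:
            wt_recs = [coloc_mod.score_cell(n, paint, config.margin_um) for n in wt]
            records.extend(wt_recs)
            wt_summaries[paint] = coloc_mod.summarize_condition(wt_recs)
    reference = tg_summaries.pop(config.reference_paint)
    calls = coloc_mod.call_linkage(
        tg_summaries, reference, alpha=config.alpha, threshold=config.coloc_threshold
    )
    if out_dir is not None:
        pd.DataFrame([asdict(r) for r in records]).to_csv(
            out_dir / "colocalization_cells.tsv", sep="\t", index=False
        )
        rows = [
            {
                "genotype": s.genotype,
                "paint_chromosome": s.paint_chromosome,
                "n_cells": s.n_cells,
                **{f"n_k{k}": v for k, v in s.counts_by_k.items()},
                "pct_ge1": s.pct_at_least[1],
                "pct_ge2": s.pct_at_least[2],
            }
            for s in [*tg_summaries.values(), reference, *wt_summaries.values()]
        ]
        pd.DataFrame(rows).to_csv(out_dir / "colocalization_summary.tsv", sep="\t", index=False)
    return {
        "tg_summaries": tg_summaries,
        "wt_summaries": wt_summaries,
        "reference": reference,
        "calls": calls,
        "linked": sorted(c for c, call in calls.items() if call.linked),
    }


@_stage("spatial_proximity")
def _run_distance(config: PipelineConfig, nuclei: list[Nucleus], out_dir: Path | None) -> dict:
    tg = [n for n in nuclei if n.genotype == "TG"]
    wt = [n for n in nuclei if n.genotype == "WT"]
    if not tg or not wt:
        raise ValueError("distance stage needs both WT and TG cells")
    normalized: dict[str, list[float]] = {}
    exclusions: dict[str, dict[str, int]] = {}
    all_records: list[dist_mod.DistanceRecord] = []
    for seg in config.segments:
        tg_recs, tg_excl = dist_mod.collect_distance_records(tg, seg)
        wt_recs, wt_excl = dist_mod.collect_distance_records(wt, seg)
        if not wt_recs or not tg_recs:
            raise ValueError(f"segment {seg!r} has no eligible cells")
        dist_mod.normalize_records(tg_recs, wt_recs)
        normalized[seg] = [r.normalized for r in tg_recs]
        exclusions[seg] = {"TG": tg_excl, "WT": wt_excl}
        all_records.extend(wt_recs + tg_recs)
    comparisons = dist_mod.compare_segments(normalized, config.reference_segment)
    ranking = dist_mod.rank_candidate_insertion_site(normalized)
    if out_dir is not None:
        pd.DataFrame([asdict(r) for r in all_records]).to_csv(
            out_dir / "distance_records.tsv", sep="\t", index=False
        )
        pd.DataFrame([asdict(c) for c in comparisons]).to_csv(
            out_dir / "segment_comparisons.tsv", sep="\t", index=False
        )
        pd.DataFrame(ranking, columns=["segment", "median_normalized_um", "tied"]).to_csv(
            out_dir / "segment_ranking.tsv", sep="\t", index=False
        )
    return {
        "normalized": normalized,
        "comparisons": comparisons,
        "ranking": ranking,
        "nearest_segment": ranking[0][0],
        "exclusions": exclusions,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all pipeline stages and return the report bundle.

    With ``de_only`` (or without spot/territory paths) only the
    silencing profile runs.  Any stage failure aborts with a
    stage-named :class:`PipelineStageError`.
    """
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    if config.de_table is None:
        raise PipelineStageError("cli_io", ValueError("no DE table configured"))

    summary: dict = {"seed": config.seed}
    bundle: dict = {}

    profile_report = _run_profile(config, out_dir)
    bundle["profile"] = profile_report
    summary["candidate_chromosomes"] = profile_report["candidates"]
    summary["candidate_chromosome"] = (
        profile_report["candidates"][0] if profile_report["candidates"] else None
    )
    summary["n_down"] = int(len(profile_report["down"]))
    summary["n_up"] = int(len(profile_report["up"]))
    summary["n_clusters"] = len(profile_report["clusters"])

    de_only = config.de_only or config.spots is None
    if not de_only:
        try:
            nuclei = io_mod.read_nuclei(config.spots, config.territories)
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineStageError("cli_io", exc) from exc
        coloc_report = _run_coloc(config, nuclei, out_dir)
        bundle["coloc"] = coloc_report
        summary["linkage_calls"] = {
            c: call.linked for c, call in coloc_report["calls"].items()
        }
        summary["linked_chromosomes"] = coloc_report["linked"]

        distance_report = _run_distance(config, nuclei, out_dir)
        bundle["distance"] = distance_report
        summary["segment_ranking"] = [seg for seg, _, _ in distance_report["ranking"]]
        summary["nearest_segment"] = distance_report["nearest_segment"]
        summary["distance_exclusions"] = distance_report["exclusions"]

    bundle["summary"] = summary
    if out_dir is not None:
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return bundle
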