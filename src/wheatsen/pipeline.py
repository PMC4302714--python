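"""End-to-end orchestration: configuration, staging, reports, manifest.

A run is driven by one flat JSON config.  In synthetic mode the run
generates its own annotation inputs and count matrix from a seed; in
data mode it consumes a count table + sample sheet (and optionally raw
placements plus a locus GFF).  Identical config and seed reproduce
identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    build_annotation,
    cluster_merge_intervals,
    detect_novel_regions,
)
from .counting import low_count_filter, count_reads, read_placements_tsv
from .diffexpr import run_all_comparisons, size_factors
from .enrichment import TermMap, fisher_enrichment
from .gene_sets import high_confidence_sets, overlap_fraction, redundancy_fraction, tally_directions
from .io import (
    load_count_table,
    read_gff,
    write_count_table,
    write_gff,
    write_sample_sheet,
)
from .model import Thresholds
from .profiles import class_fractions, classify_profiles, profile_table
from .report import family_report, read_family_map
from .simulate import SimulationConfig, simulate_annotation_inputs, simulate_counts

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, naming the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | os.PathLike) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


def thresholds_from_config(config: dict[str, Any]) -> Thresholds:
    fields = {f.name for f in dataclasses.fields(Thresholds)}
    given = {k: v for k, v in config.get("thresholds", {}).items() if k in fields}
    unknown = set(config.get("thresholds", {})) - fields
    if unknown:
        raise ValueError(f"unknown threshold fields: {sorted(unknown)}")
    return Thresholds(**given)


def run_pipeline(config: dict[str, Any] | str | os.PathLike, outdir: str | os.PathLike) -> Path:
    """Execute the full analysis and write all reports under ``outdir``."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = thresholds_from_config(config)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config,
        "thresholds": dataclasses.asdict(th),
        "stages": {},
    }

    # --- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.get("synthetic", True):
            sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_kwargs = {k: v for k, v in config.get("simulation", {}).items() if k in sim_fields}
            sim_kwargs.setdefault("seed", int(config.get("seed", 0)))
            cfg = SimulationConfig(**sim_kwargs)
            cm, truth = simulate_counts(cfg)
            truth.table.to_csv(out / "truth_labels.tsv", sep="\t")
            write_count_table(cm, out / "raw_counts.tsv")
            write_sample_sheet(cm.samples, out / "sample_sheet.tsv")
            fragments, coverage, truth_loci = simulate_annotation_inputs(cfg)
            transcript_merged = cluster_merge_intervals(
                [iv for iv, _tag in fragments], max_gap=th.transcript_cluster_gap
            )
            from .model import Locus, LocusSet, LocusSource

            transcript_ls = LocusSet(
                Locus(Locus.auto_id(iv), iv) for iv in transcript_merged
            )
            novel = detect_novel_regions(
                coverage, th.novel_min_depth, th.novel_cluster_gap, transcript_ls
            )
            annotation = build_annotation(transcript_merged, novel)
            write_gff(annotation, out / "annotation.gff3")
            manifest["stages"]["annotation"] = {
                "transcript_loci": len(transcript_merged),
                "novel_loci": len(novel),
                "total_loci": len(annotation),
                "truth_loci": len(truth_loci),
            }
        else:
            if "count_table" not in config or "sample_sheet" not in config:
                raise ValueError("config missing 'count_table' or 'sample_sheet'")
            cm = load_count_table(config["count_table"], config["sample_sheet"])
            if "placements" in config and "annotation_gff" in config:
                loci = read_gff(config["annotation_gff"])
                placements = read_placements_tsv(config["placements"])
                cm, stats_ = count_reads(placements, loci, cm.samples)
                manifest["stages"]["counting"] = dataclasses.asdict(stats_)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    manifest["stages"]["inputs"] = {"n_loci": cm.n_loci, "n_samples": cm.n_samples}

    # --- filter + normalize ----------------------------------------------
    stage = "filter"
    try:
        retained, removed = low_count_filter(cm, th)
        pd.Series(removed, name="locus_id").to_csv(out / "removed_loci.tsv", sep="\t", index=False)
        factors = size_factors(retained, allow_positive_fallback=True)
        pd.DataFrame(
            {"sample_id": [s.sample_id for s in retained.samples], "size_factor": factors}
        ).to_csv(out / "size_factors.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    manifest["stages"]["filter"] = {
        "input_loci": cm.n_loci,
        "retained": retained.n_loci,
        "removed": len(removed),
    }

    # --- comparisons ------------------------------------------------------
    stage = "comparisons"
    try:
        all_results = run_all_comparisons(retained, th)
        comp_dir = out / "comparisons"
        comp_dir.mkdir(exist_ok=True)
        for label, result in all_results.results.items():
            safe = label.replace(":", "__")
            result.table.rename_axis("locus_id").to_csv(comp_dir / f"{safe}.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    manifest["stages"]["comparisons"] = {
        label: int(r.table["is_de"].sum()) for label, r in all_results.results.items()
    }
    manifest["stages"]["genotype_sets"] = {
        label: len(ids) for label, ids in all_results.genotype_sets.items()
    }

    # --- profiles ---------------------------------------------------------
    stage = "profiles"
    try:
        r12, r02, r22 = all_results.wt_time_results()
        assignments = classify_profiles(r12, r22, r02)
        profile_table(assignments).to_csv(out / "profile_assignments.tsv", sep="\t")
        class_fractions(assignments).rename_axis("profile_class").to_csv(
            out / "profile_class_fractions.tsv", sep="\t"
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    manifest["stages"]["profiles"] = {"assigned": len(assignments)}

    # --- set algebra ------------------------------------------------------
    stage = "sets"
    try:
        report = high_confidence_sets(all_results.genotype_sets)
        sen = all_results.senescence_de_ids
        n1, f1 = overlap_fraction(report.hc_gpc1, sen)
        n2, f2 = overlap_fraction(report.hc_gpc2, sen)
        cells = report.venn_cells()
        redundancy = redundancy_fraction(
            cells["D_only"],
            cells["A_and_B_and_D"],
            cells["A_only"] + cells["A_and_D_only"],
            cells["B_only"] + cells["B_and_D_only"],
        )
        set_summary = {
            "counts": report.counts(),
            "venn_cells": cells,
            "senescence_de": len(sen),
            "hc_gpc1_senescence_overlap": {"n": n1, "pct_of_hc": f1},
            "hc_gpc2_senescence_overlap": {"n": n2, "pct_of_hc": f2},
            "redundancy_pct": redundancy,
            "wt_time_tallies": {
                label: dict(
                    zip(("n_up", "n_down", "pct_up", "pct_down"), tally_directions(r))
                )
                for label, r in (
                    (r12.label, r12),
                    (r22.label, r22),
                    (r02.label, r02),
                )
            },
        }
        with open(out / "set_report.json", "w") as fh:
            json.dump(set_summary, fh, indent=2, sort_keys=True, allow_nan=True)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    manifest["stages"]["sets"] = report.counts()

    # --- enrichment -------------------------------------------------------
    stage = "enrichment"
    try:
        if "term_map" in config:
            tm = TermMap.from_tsv(config["term_map"], config.get("term_labels"))
            universe = set(retained.locus_ids)
            for name, gene_set in (
                ("senescence_up", {i for i in sen if _is_up(all_results, i)}),
                ("senescence_down", {i for i in sen if not _is_up(all_results, i)}),
                ("hc_gpc1", report.hc_gpc1),
                ("hc_gpc2", report.hc_gpc2),
            ):
                if gene_set and (gene_set & tm.annotated_universe()):
                    table = fisher_enrichment(gene_set & tm.annotated_universe(), universe, tm)
                    table.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- family report ----------------------------------------------------
    stage = "family_report"
    try:
        if "family_map" in config:
            fam = read_family_map(config["family_map"])
            family_report(retained, all_results, fam, factors=factors).to_csv(
                out / "family_report.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _is_up(all_results, locus_id: str) -> bool:
    from .diffexpr import WT_TIME_LABELS

    for label in WT_TIME_LABELS:
        row = all_results.results[label].table.loc[locus_id]
        if row["is_de"]:
            return row["direction"] == "up"
    return False


def tree_checksum(root: str | os.PathLike) -> str:
    """SHA-256 over every file (path + content) under a directory."""
    h = hashlib.sha256()
    for path in sorted(Path(root).rglob("*")):
        if path.is_file():
            h.update(str(path.relative_to(root)).encode())
            h.update(path.read_bytes())
    return h.hexdigest()
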