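"""Readers and writers for the flat text formats the pipeline touches.

GFF3 for the locus annotation, BED for intervals and read placements,
TSV for coverage tracks, count tables and sample sheets.  The GFF files
here carry a single feature type over unique ids, so they are parsed
directly line by line; coordinate conversion between GFF3 (1-based
inclusive) and the internal convention (0-based half-open) happens only
in this module.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    CountMatrix,
    Genotype,
    GenomicInterval,
    Locus,
    LocusSet,
    LocusSource,
    SampleDescriptor,
    Timepoint,
)

GFF_FEATURE_TYPE = "transcribed_region"
GFF_SOURCE_FIELD = "wheatsen"


class GffParseError(ValueError):
    """Raised for a malformed GFF3 line, carrying the line number."""


def read_gff(path: str | os.PathLike) -> LocusSet:
    """Read a locus annotation track from GFF3.

    GFF3 coordinates are 1-based inclusive; they are converted to the
    internal 0-based half-open convention (start-1, end).  The locus id is
    taken from the ``ID`` attribute; the ``source`` attribute, when
    present, restores the transcript/coverage provenance tag.
    """
    loci: list[Locus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            contig, _src, _type, start_s, end_s, _score, _strand, _frame, attrs = fields
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GffParseError(f"line {lineno}: end {end1} < start {start1}")
            attr_map = _parse_attributes(attrs, lineno)
            locus_id = attr_map.get("ID")
            interval = GenomicInterval(contig, start1 - 1, end1)
            if locus_id is None:
                locus_id = Locus.auto_id(interval)
            source = LocusSource(attr_map.get("source", LocusSource.transcript_derived.value))
            loci.append(Locus(locus_id, interval, source))
    return LocusSet(loci)


def _parse_attributes(attrs: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise GffParseError(f"line {lineno}: malformed attribute {item!r}")
        key, value = item.split("=", 1)
        out[key] = value
    return out


def write_gff(ls: LocusSet, path: str | os.PathLike) -> None:
    """Write a LocusSet as GFF3 (1-based inclusive, strandless)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in ls:
            iv = locus.interval
            attrs = f"ID={locus.locus_id};source={locus.source.value}"
            fh.write(
                "\t".join(
                    [
                        iv.contig_id,
                        GFF_SOURCE_FIELD,
                        GFF_FEATURE_TYPE,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED intervals and read placements


def read_bed_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read plain BED3 (0-based half-open, like the internal convention)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed_intervals(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Coverage tracks: TSV of (contig, pos, depth), zero depth omitted


def write_coverage(coverage: dict[str, np.ndarray], path: str | os.PathLike) -> None:
    frames = []
    for contig in sorted(coverage):
        depth = np.asarray(coverage[contig])
        pos = np.nonzero(depth)[0]
        frames.append(
            pd.DataFrame({"contig": contig, "pos": pos, "depth": depth[pos]})
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["contig", "pos", "depth"])
    )
    out.to_csv(path, sep="\t", index=False)


def read_coverage(path: str | os.PathLike, contig_length: int | None = None) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, np.ndarray] = {}
    for contig, grp in df.groupby("contig"):
        n = contig_length if contig_length is not None else int(grp["pos"].max()) + 1
        depth = np.zeros(n, dtype=np.int64)
        depth[grp["pos"].to_numpy()] = grp["depth"].to_numpy()
        out[str(contig)] = depth
    return out


# ---------------------------------------------------------------------------
# Count tables and sample sheets


def write_count_table(cm: CountMatrix, path: str | os.PathLike) -> None:
    cm.counts.rename_axis("locus_id").to_csv(path, sep="\t")


def write_sample_sheet(samples: Sequence[SampleDescriptor], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "genotype": [s.genotype.value for s in samples],
            "timepoint": [s.timepoint.value for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | os.PathLike) -> dict[str, SampleDescriptor]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": int})
    required = {"sample_id", "genotype", "timepoint", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    out: dict[str, SampleDescriptor] = {}
    for row in df.itertuples(index=False):
        out[str(row.sample_id)] = SampleDescriptor(
            Genotype(row.genotype), Timepoint(row.timepoint), int(row.replicate)
        )
    return out


def load_count_table(
    path: str | os.PathLike,
    sample_sheet: str | os.PathLike,
    min_replicates_warn: int = 2,
) -> CountMatrix:
    """Load a TSV count table against a sample sheet.

    Float entries that are whole numbers (e.g. "3.0") are coerced to
    integers; fractional or negative entries are rejected.  Every column
    of the table must appear in the sheet.  Design cells with fewer than
    ``min_replicates_warn`` samples trigger a warning, not an error.
    """
    import warnings

    sheet = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [c for c in df.columns if c not in sheet]
    if unknown:
        raise ValueError(f"samples in count table absent from sample sheet: {unknown}")
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("count table contains missing values")
    if (arr < 0).any():
        raise ValueError("count table contains negative values")
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, atol=1e-9):
        raise ValueError("count table contains non-integer values")
    counts = pd.DataFrame(rounded.astype(np.int64), index=df.index, columns=df.columns)
    samples = [sheet[c] for c in counts.columns]
    cm = CountMatrix(counts, samples)
    for (g, t), cols in cm.design_cells().items():
        if len(cols) < min_replicates_warn:
            warnings.warn(
                f"design cell {g.value}/{t.value} has only {len(cols)} sample(s)",
                stacklevel=2,
            )
    return cm
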