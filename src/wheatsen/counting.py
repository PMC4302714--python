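"""Assigning uniquely mapped read placements to loci and low-count filtering.

Counting follows union-mode semantics over a disjoint locus track: a
uniquely mapped placement overlapping exactly one locus (by at least one
base) increments that locus for its sample; placements that are
non-unique, overlap no locus, or straddle more than one locus contribute
nothing.  Uniqueness is an input flag carried by each placement, not
recomputed here; an adapter for SAM-derived data should set it from
``NH == 1`` or a MAPQ cutoff.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import CountMatrix, LocusSet, SampleDescriptor, Thresholds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadPlacement:
    """One aligned read: where it landed and whether the mapping was unique."""

    contig_id: str
    start: int
    end: int
    sample_id: str
    unique: bool

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty placement [{self.start}, {self.end})")


@dataclass
class CountingStats:
    """Bookkeeping for one counting run; categories partition the input."""

    assigned: int = 0
    nonunique: int = 0
    unassigned: int = 0
    ambiguous: int = 0
    unknown_contig: int = 0

    @property
    def total(self) -> int:
        return self.assigned + self.nonunique + self.unassigned + self.ambiguous + self.unknown_contig

    def unique_fraction(self) -> float:
        """Fraction of placements carrying the unique flag."""
        return 1.0 - self.nonunique / self.total if self.total else float("nan")


def count_reads(
    placements: Iterable[ReadPlacement],
    loci: LocusSet,
    samples: Sequence[SampleDescriptor],
) -> tuple[CountMatrix, CountingStats]:
    """Union-mode counting of unique placements over a disjoint locus track."""
    by_contig = loci.by_contig()
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    ids: dict[str, list[str]] = {}
    for contig, contig_loci in by_contig.items():
        starts[contig] = [l.interval.start for l in contig_loci]
        ends[contig] = [l.interval.end for l in contig_loci]
        ids[contig] = [l.locus_id for l in contig_loci]

    sample_index = {s.sample_id: j for j, s in enumerate(samples)}
    locus_index = {lid: i for i, lid in enumerate(loci.locus_ids)}
    counts = np.zeros((len(loci), len(samples)), dtype=np.int64)
    stats = CountingStats()

    for p in placements:
        if p.sample_id not in sample_index:
            raise ValueError(f"placement sample {p.sample_id!r} not in design")
        if not p.unique:
            stats.nonunique += 1
            continue
        if p.contig_id not in starts:
            stats.unknown_contig += 1
            logger.warning("placement on unknown contig %s", p.contig_id)
            continue
        s, e, lid = starts[p.contig_id], ends[p.contig_id], ids[p.contig_id]
        # loci with start < p.end can overlap; they are disjoint and sorted,
        # so the overlapping ones sit contiguously just below hi
        hi = bisect.bisect_left(s, p.end)
        hits = []
        for k in range(hi - 1, -1, -1):
            if e[k] > p.start:
                hits.append(k)
            else:
                break
        if len(hits) == 0:
            stats.unassigned += 1
        elif len(hits) == 1:
            counts[locus_index[lid[hits[0]]], sample_index[p.sample_id]] += 1
            stats.assigned += 1
        else:
            stats.ambiguous += 1

    cm = CountMatrix(
        pd.DataFrame(counts, index=loci.locus_ids, columns=[s_.sample_id for s_ in samples]),
        samples,
    )
    return cm, stats


def read_placements_tsv(path) -> list[ReadPlacement]:
    """BED6-like placements: contig, start, end, sample_id, unique (0/1)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["contig", "start", "end", "sample_id", "unique"],
        comment="#",
    )
    return [
        ReadPlacement(str(r.contig), int(r.start), int(r.end), str(r.sample_id), bool(int(r.unique)))
        for r in df.itertuples(index=False)
    ]


def low_count_filter(
    cm: CountMatrix, th: Thresholds
) -> tuple[CountMatrix, list[str]]:
    """Retain loci with evidence of expression in at least one design cell.

    A locus is retained iff some genotype x timepoint cell contains at
    least ``retain_min_replicates`` replicates whose counts each strictly
    exceed ``retain_min_reads_exclusive`` (the study rule: more than three
    reads in at least two biological replicates of one cell).
    """
    arr = cm.counts.to_numpy()
    keep = np.zeros(cm.n_loci, dtype=bool)
    for cols in cm.design_cells().values():
        n_supporting = (arr[:, cols] > th.retain_min_reads_exclusive).sum(axis=1)
        keep |= n_supporting >= th.retain_min_replicates
    retained = CountMatrix(cm.counts.loc[keep], cm.samples)
    removed_ids = list(cm.counts.index[~keep])
    logger.info(
        "low-count filter: %d loci in, %d retained, %d removed",
        cm.n_loci, retained.n_loci, len(removed_ids),
    )
    return retained, removed_ids
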