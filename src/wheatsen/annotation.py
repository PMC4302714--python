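"""Building the putative transcribed-locus annotation track.

Transcript-to-genome alignment intervals are cluster-merged into disjoint
transcribed regions; regions of high read coverage outside those loci are
added as novel, coverage-derived loci.  Merging is per contig and never
crosses contigs; on half-open coordinates two intervals merge when
``start_next - end_prev <= max_gap``, so bookended intervals (gap 0)
merge even at ``max_gap=0``, matching overlapping-or-bookended cluster
semantics.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import GenomicInterval, Locus, LocusSet, LocusSource


def cluster_merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose separation is at most ``max_gap`` bp.

    Returns the minimal disjoint set of intervals covering the input, one
    output interval per chain of inputs linked by gaps <= max_gap.
    Output is sorted by (contig, start); merging never crosses contigs.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if (
            merged
            and merged[-1].contig_id == iv.contig_id
            and iv.start - merged[-1].end <= max_gap
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.contig_id, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def detect_novel_regions(
    coverage: Mapping[str, np.ndarray],
    min_depth: int,
    cluster_gap: int,
    existing: LocusSet,
) -> list[GenomicInterval]:
    """Find coverage-supported transcribed regions outside known loci.

    Per contig: (1) positions inside ``existing`` loci are masked out,
    (2) maximal runs of depth >= ``min_depth`` become candidates,
    (3) candidates are cluster-merged with ``max_gap=cluster_gap``.

    ``coverage`` maps contig id to a per-base depth array.  When several
    tracks are available they should be combined into one array before the
    call (this pipeline takes the per-position maximum across tracks, see
    :func:`combine_coverage_tracks`).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    existing_by_contig = existing.by_contig()
    candidates: list[GenomicInterval] = []
    for contig, depth in coverage.items():
        depth = np.asarray(depth)
        if (depth < 0).any():
            raise ValueError(f"negative coverage on {contig}")
        mask = depth >= min_depth
        for locus in existing_by_contig.get(contig, []):
            mask[locus.interval.start : locus.interval.end] = False
        candidates.extend(
            GenomicInterval(contig, s, e) for s, e in _runs(mask)
        )
    return cluster_merge_intervals(candidates, max_gap=cluster_gap)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of consecutive True values."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def combine_coverage_tracks(tracks: Sequence[Mapping[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Per-position maximum depth across coverage tracks.

    A region counts as transcribed if any track supports it at depth; the
    maximum is the least lossy combination rule for a detection threshold.
    """
    combined: dict[str, np.ndarray] = {}
    for track in tracks:
        for contig, depth in track.items():
            depth = np.asarray(depth)
            if contig in combined:
                n = max(len(combined[contig]), len(depth))
                a = np.zeros(n, dtype=depth.dtype)
                a[: len(combined[contig])] = combined[contig]
                a[: len(depth)] = np.maximum(a[: len(depth)], depth)
                combined[contig] = a
            else:
                combined[contig] = depth.copy()
    return combined


def build_annotation(
    transcript_loci: Sequence[GenomicInterval],
    novel_loci: Sequence[GenomicInterval],
) -> LocusSet:
    """Combine transcript-derived and coverage-derived loci into one track.

    The two groups must already be internally disjoint and disjoint from
    each other (novel detection masks existing loci, so an overlap here
    signals that masking was skipped).  The result has exactly
    ``len(transcript_loci) + len(novel_loci)`` loci, tagged by source.
    """
    loci = [
        Locus(Locus.auto_id(iv), iv, LocusSource.transcript_derived)
        for iv in transcript_loci
    ] + [
        Locus(Locus.auto_id(iv), iv, LocusSource.coverage_derived)
        for iv in novel_loci
    ]
    ls = LocusSet(loci)
    prev: Locus | None = None
    for locus in ls:
        if prev is not None and prev.interval.overlaps(locus.interval):
            raise ValueError(
                f"overlapping loci {prev.locus_id} and {locus.locus_id}: "
                "inputs to build_annotation must be disjoint"
            )
        prev = locus
    return ls
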