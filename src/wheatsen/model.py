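"""Core domain types shared by the whole pipeline.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.  Loci are strandless merged genomic ranges, so strand is not
modelled anywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Locus",
    "LocusSet",
    "Genotype",
    "Timepoint",
    "SampleDescriptor",
    "CountMatrix",
    "Thresholds",
    "DEFAULT_THRESHOLDS",
]


class Genotype(str, enum.Enum):
    """The three genotypes of the senescence time course."""

    WT = "WT"
    gpcA1 = "gpcA1"
    gpcA1_gpcB2 = "gpcA1_gpcB2"


class Timepoint(str, enum.Enum):
    """Sampling times: heading date, 12 and 22 days after anthesis."""

    HD = "HD"
    D12 = "12DAA"
    D22 = "22DAA"


#: Natural temporal order of the three sampling times.
TIMEPOINT_ORDER = (Timepoint.HD, Timepoint.D12, Timepoint.D22)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contiguous genomic range, 0-based half-open [start, end)."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.contig_id}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.contig_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Separation in bp to another interval on the same contig.

        Overlapping intervals have negative gap; bookended intervals have
        gap 0.
        """
        if self.contig_id != other.contig_id:
            raise ValueError("gap undefined across contigs")
        if self.start <= other.start:
            return other.start - self.end
        return self.start - other.end


class LocusSource(str, enum.Enum):
    transcript_derived = "transcript_derived"
    coverage_derived = "coverage_derived"


@dataclass(frozen=True)
class Locus:
    """A putative transcribed region used as a counting unit."""

    locus_id: str
    interval: GenomicInterval
    source: LocusSource = LocusSource.transcript_derived

    @staticmethod
    def auto_id(interval: GenomicInterval) -> str:
        return f"{interval.contig_id}:{interval.start}-{interval.end}"


class LocusSet:
    """An ordered collection of loci, sorted by (contig, start).

    Locus ids must be unique.  Disjointness of loci on a contig is a
    property of annotation building, not of the container, and is checked
    there.
    """

    def __init__(self, loci: Iterable[Locus]):
        loci = sorted(loci, key=lambda l: (l.interval.contig_id, l.interval.start, l.interval.end))
        seen: set[str] = set()
        for locus in loci:
            if locus.locus_id in seen:
                raise ValueError(f"duplicate locus_id {locus.locus_id!r}")
            seen.add(locus.locus_id)
        self._loci: list[Locus] = loci

    def __len__(self) -> int:
        return len(self._loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self._loci)

    def __getitem__(self, i: int) -> Locus:
        return self._loci[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocusSet):
            return NotImplemented
        return self._loci == other._loci

    def __repr__(self) -> str:
        return f"LocusSet(n={len(self)})"

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self._loci]

    def intervals(self) -> list[GenomicInterval]:
        return [l.interval for l in self._loci]

    def by_contig(self) -> dict[str, list[Locus]]:
        out: dict[str, list[Locus]] = {}
        for locus in self._loci:
            out.setdefault(locus.interval.contig_id, []).append(locus)
        return out


@dataclass(frozen=True, order=True)
class SampleDescriptor:
    """One RNA-seq library: genotype x timepoint x replicate."""

    genotype: Genotype
    timepoint: Timepoint
    replicate: int

    @property
    def sample_id(self) -> str:
        return f"{self.genotype.value}_{self.timepoint.value}_r{self.replicate}"


def full_design(n_replicates: int = 4) -> list[SampleDescriptor]:
    """The study design: 3 genotypes x 3 timepoints x R replicates."""
    return [
        SampleDescriptor(g, t, r)
        for g in Genotype
        for t in TIMEPOINT_ORDER
        for r in range(1, n_replicates + 1)
    ]


class CountMatrix:
    """Integer read counts, loci x samples, with design metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by locus_id with one column per sample_id.
    samples
        The ordered sample descriptors, one per counts column.
    """

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleDescriptor]):
        if counts.shape[1] != len(samples):
            raise ValueError(
                f"{counts.shape[1]} count columns but {len(samples)} sample descriptors"
            )
        expected = [s.sample_id for s in samples]
        if list(counts.columns) != expected:
            raise ValueError("count columns do not match sample descriptors in order")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            as_int = np.rint(arr).astype(np.int64)
            if not np.allclose(arr, as_int):
                raise ValueError("counts must be integers")
            counts = pd.DataFrame(as_int, index=counts.index, columns=counts.columns)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.index.has_duplicates:
            raise ValueError("duplicate locus ids in count matrix")
        self.counts = counts
        self.samples = list(samples)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_loci(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "genotype": [s.genotype.value for s in self.samples],
                "timepoint": [s.timepoint.value for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def columns_for(
        self, genotype: Genotype | None = None, timepoint: Timepoint | None = None
    ) -> list[int]:
        """Column indices of samples matching the given cell (or margin)."""
        return [
            j
            for j, s in enumerate(self.samples)
            if (genotype is None or s.genotype == genotype)
            and (timepoint is None or s.timepoint == timepoint)
        ]

    def design_cells(self) -> dict[tuple[Genotype, Timepoint], list[int]]:
        cells: dict[tuple[Genotype, Timepoint], list[int]] = {}
        for j, s in enumerate(self.samples):
            cells.setdefault((s.genotype, s.timepoint), []).append(j)
        return cells

    def subset_loci(self, locus_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(locus_ids)], self.samples)


@dataclass(frozen=True)
class Thresholds:
    """Every tunable cutoff of the pipeline, defaulting to the study values.

    ``retain_min_reads_exclusive`` is an exclusive bound: a replicate
    supports retention only with count strictly greater than it (>3, i.e.
    at least 4 reads).
    """

    retain_min_reads_exclusive: int = 3
    retain_min_replicates: int = 2
    fdr_alpha: float = 0.01
    mww_alpha: float = 0.05
    t_alpha: float = 0.01
    novel_min_depth: int = 10
    novel_cluster_gap: int = 1000
    transcript_cluster_gap: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_alpha", "mww_alpha", "t_alpha"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name}={a} outside (0, 1)")
        if self.novel_min_depth < 1:
            raise ValueError("novel_min_depth must be >= 1")
        if self.novel_cluster_gap < 0 or self.transcript_cluster_gap < 0:
            raise ValueError("cluster gaps must be >= 0")
        if self.retain_min_replicates < 1:
            raise ValueError("retain_min_replicates must be >= 1")


DEFAULT_THRESHOLDS = Thresholds()
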