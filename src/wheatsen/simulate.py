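"""Synthetic data with planted truth for the senescence pipeline.

Two generators:

* :func:`simulate_counts` draws a negative-binomial count matrix over the
  3-genotype x 3-timepoint x 4-replicate design with planted
  senescence-regulated loci (one of eight Up/Down/Flat temporal classes
  in WT) and planted regulator labels (GPC1-only, GPC2-only, redundant)
  that suppress the temporal response in the corresponding mutant
  genotypes;
* :func:`simulate_annotation_inputs` emits fragmented transcript
  alignment intervals and read-coverage tracks around planted truth loci
  so the annotation builder can be tested for exact boundary recovery.

The regulator model: a GPC1-regulated locus loses its temporal response
in both mutant genotypes (GPC1 is required and its loss is epistatic); a
GPC2-regulated locus responds normally in the single gpc-A1 mutant (GPC2
is intact there) and is flat only in the double mutant; a redundantly
regulated locus is flat in the double mutant and shows a half-strength
response (log-fold profile scaled by 0.5) in the single mutant.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .model import (
    CountMatrix,
    Genotype,
    GenomicInterval,
    LocusSet,
    SampleDescriptor,
    Timepoint,
    TIMEPOINT_ORDER,
    full_design,
)
from .profiles import PROFILE_CLASSES

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "simulate_counts",
    "simulate_annotation_inputs",
    "simulate_term_map",
]

_STEP = {"Up": 1.0, "Down": -1.0, "Flat": 0.0}

#: Fraction of the WT log-fold profile retained by the single gpc-A1
#: mutant at redundantly regulated loci (GPC2 compensates only partially).
REDUNDANT_ATTENUATION = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the planted-truth count simulation.

    Defaults describe a 2,000-locus experiment over the full study design
    with moderately to highly expressed loci (baseline means log-uniform
    in [100, 2000] normalized counts — the regime that survives the
    low-count filter), locus-wise NB dispersion log-uniform in
    [0.01, 0.1], per-sample library-size factors uniform in [0.5, 2], and
    planted |log2 fold changes| of 2 per temporal transition.
    """

    n_loci: int = 2000
    n_contigs: int = 4
    contig_length: int = 100_000
    n_replicates: int = 4
    seed: int = 0
    baseline_mean_log_range: tuple[float, float] = (np.log(100.0), np.log(2000.0))
    dispersion_range: tuple[float, float] = (0.01, 0.1)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    frac_senescence_de: float = 0.3
    profile_class_weights: tuple[float, ...] = (0.125,) * 8
    frac_gpc1_only: float = 0.15
    frac_gpc2_only: float = 0.10
    frac_redundant: float = 0.20
    effect_size_log2fc: float = 2.0
    # annotation-input knobs
    n_truth_loci: int = 10
    n_coverage_only: int = 3
    locus_length_range: tuple[int, int] = (200, 2000)
    novel_depth_range: tuple[int, int] = (15, 40)
    background_depth_max: int = 3

    def __post_init__(self) -> None:
        for frac in (self.frac_senescence_de, self.frac_gpc1_only, self.frac_gpc2_only, self.frac_redundant):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.frac_gpc1_only + self.frac_gpc2_only + self.frac_redundant > 1.0 + 1e-12:
            raise ValueError("regulator fractions must sum to <= 1")
        if len(self.profile_class_weights) != 8:
            raise ValueError("profile_class_weights needs 8 entries")
        if abs(sum(self.profile_class_weights) - 1.0) > 1e-9:
            raise ValueError("profile_class_weights must sum to 1")
        if self.n_replicates < 2:
            raise ValueError("design needs >= 2 replicates per cell")

    def design(self) -> list[SampleDescriptor]:
        return full_design(self.n_replicates)


@dataclass
class TruthLabels:
    """Planted ground truth, one row per locus.

    Columns: ``is_senescence_de`` (bool), ``profile_class`` (one of the
    eight class names or ""), ``regulator`` (none/GPC1/GPC2/redundant),
    ``baseline_mean``, ``dispersion``.
    """

    table: pd.DataFrame
    size_factors: np.ndarray

    def de_ids(self) -> set[str]:
        return set(self.table.index[self.table["is_senescence_de"]])

    def ids_with_regulator(self, regulator: str) -> set[str]:
        return set(self.table.index[self.table["regulator"] == regulator])


def _profile_log2_factors(profile_class: str, effect: float) -> np.ndarray:
    """Cumulative log2 expression offsets at (HD, 12DAA, 22DAA) in WT."""
    t1, t2 = profile_class.split("-")
    return np.array([0.0, _STEP[t1] * effect, (_STEP[t1] + _STEP[t2]) * effect])


def _genotype_profile(
    wt_log2: np.ndarray, regulator: str, genotype: Genotype
) -> np.ndarray:
    if genotype == Genotype.WT or regulator == "none":
        return wt_log2
    if regulator == "GPC1":
        return np.zeros(3)
    if regulator == "GPC2":
        return wt_log2 if genotype == Genotype.gpcA1 else np.zeros(3)
    if regulator == "redundant":
        if genotype == Genotype.gpcA1:
            return wt_log2 * REDUNDANT_ATTENUATION
        return np.zeros(3)
    raise ValueError(f"unknown regulator {regulator!r}")


def expected_mean(
    baseline: float,
    profile_class: str,
    regulator: str,
    genotype: Genotype,
    timepoint: Timepoint,
    effect: float,
) -> float:
    """Planted mean (before size factors) for one locus in one design cell."""
    if profile_class == "":
        return baseline
    wt_log2 = _profile_log2_factors(profile_class, effect)
    log2 = _genotype_profile(wt_log2, regulator, genotype)
    t_idx = TIMEPOINT_ORDER.index(timepoint)
    return baseline * 2.0 ** log2[t_idx]


def simulate_counts(cfg: SimulationConfig) -> tuple[CountMatrix, TruthLabels]:
    """Draw a count matrix with planted senescence and regulator structure.

    Counts for locus i in sample j are NB with mean
    ``s_j * mu_i * f_i(genotype_j, timepoint_j)`` and locus dispersion
    ``alpha_i`` (variance ``m + alpha m^2``).  Identical configs (same
    seed) give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    design = cfg.design()
    n = cfg.n_loci

    lo, hi = cfg.baseline_mean_log_range
    baseline = np.exp(rng.uniform(lo, hi, size=n))
    d_lo, d_hi = cfg.dispersion_range
    dispersion = np.exp(rng.uniform(np.log(d_lo), np.log(d_hi), size=n))
    s_lo, s_hi = cfg.size_factor_range
    factors = rng.uniform(s_lo, s_hi, size=len(design))

    n_de = int(round(cfg.frac_senescence_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    profile_class = np.full(n, "", dtype=object)
    if n_de:
        classes = rng.choice(
            PROFILE_CLASSES, size=n_de, p=np.asarray(cfg.profile_class_weights)
        )
        profile_class[de_idx] = classes

    regulator = np.full(n, "none", dtype=object)
    if n_de:
        shuffled = rng.permutation(de_idx)
        n1 = int(round(cfg.frac_gpc1_only * n_de))
        n2 = int(round(cfg.frac_gpc2_only * n_de))
        nr = int(round(cfg.frac_redundant * n_de))
        regulator[shuffled[:n1]] = "GPC1"
        regulator[shuffled[n1 : n1 + n2]] = "GPC2"
        regulator[shuffled[n1 + n2 : n1 + n2 + nr]] = "redundant"

    locus_ids = [f"locus_{i:05d}" for i in range(n)]
    counts = np.empty((n, len(design)), dtype=np.int64)
    means = np.empty((n, len(design)))
    for j, sample in enumerate(design):
        for i in range(n):
            means[i, j] = factors[j] * expected_mean(
                baseline[i],
                profile_class[i],
                regulator[i],
                sample.genotype,
                sample.timepoint,
                cfg.effect_size_log2fc,
            )
    # NB(mean m, dispersion a): size r = 1/a, p = r/(r+m); a -> 0 is Poisson
    small = dispersion < 1e-12
    r = np.where(small, 1.0, 1.0 / np.where(small, 1.0, dispersion))
    for j in range(len(design)):
        m = means[:, j]
        p = r / (r + m)
        col = np.where(
            small, rng.poisson(m), rng.negative_binomial(r, np.clip(p, 1e-300, 1.0))
        )
        counts[:, j] = col

    cm = CountMatrix(
        pd.DataFrame(counts, index=locus_ids, columns=[s.sample_id for s in design]),
        design,
    )
    truth = TruthLabels(
        pd.DataFrame(
            {
                "is_senescence_de": profile_class != "",
                "profile_class": profile_class,
                "regulator": regulator,
                "baseline_mean": baseline,
                "dispersion": dispersion,
            },
            index=locus_ids,
        ),
        factors,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Annotation inputs


def simulate_annotation_inputs(
    cfg: SimulationConfig,
) -> tuple[list[tuple[GenomicInterval, str]], dict[str, np.ndarray], LocusSet]:
    """Transcript fragments and coverage tracks around planted truth loci.

    Truth loci are placed with inter-locus gaps strictly greater than the
    1 kb novel-region clustering distance, so distinct loci can never be
    merged together.  Each transcript-supported locus is tiled by two to
    five overlapping alignment fragments whose union is exactly the locus.
    The last ``n_coverage_only`` loci get no fragments; instead their
    positions carry read depth at or above the novel-region threshold
    (Poisson around a per-locus depth, floored at the threshold so the
    planted locus is detectable end to end).  Background depth elsewhere
    is below the threshold.

    Returns (fragments with a tag of their truth locus id, coverage per
    contig, truth LocusSet).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_truth_loci
    if cfg.n_coverage_only > n:
        raise ValueError("n_coverage_only cannot exceed n_truth_loci")
    min_gap = 1500  # > the 1 kb clustering distance, with margin
    len_lo, len_hi = cfg.locus_length_range

    per_contig = -(-n // cfg.n_contigs)  # ceil division
    needed = per_contig * (len_hi + 2 * min_gap) + min_gap
    if cfg.contig_length < needed:
        raise ValueError(
            f"contig_length {cfg.contig_length} too small for {n} loci "
            f"(need >= {needed})"
        )

    truth_intervals: list[GenomicInterval] = []
    for k in range(n):
        contig = f"contig_{k % cfg.n_contigs}"
        slot = k // cfg.n_contigs
        base = min_gap + slot * (len_hi + 2 * min_gap)
        start = base + int(rng.integers(0, min_gap))
        length = int(rng.integers(len_lo, len_hi + 1))
        truth_intervals.append(GenomicInterval(contig, start, start + length))
    truth_intervals.sort()

    coverage_only = set(range(n - cfg.n_coverage_only, n))
    fragments: list[tuple[GenomicInterval, str]] = []
    coverage: dict[str, np.ndarray] = {
        f"contig_{c}": rng.integers(
            0, cfg.background_depth_max + 1, size=cfg.contig_length
        ).astype(np.int64)
        for c in range(cfg.n_contigs)
    }
    truth_ids: list[str] = []
    for idx, iv in enumerate(truth_intervals):
        locus_id = f"truth_{idx:03d}"
        truth_ids.append(locus_id)
        if idx in coverage_only:
            lam = int(rng.integers(*cfg.novel_depth_range))
            depth = rng.poisson(lam, size=iv.length)
            depth = np.maximum(depth, 10)  # stay detectable across the locus
            coverage[iv.contig_id][iv.start : iv.end] = depth
        else:
            n_frag = int(rng.integers(2, 6))
            cuts = np.sort(rng.integers(iv.start + 1, iv.end, size=n_frag - 1))
            bounds = np.concatenate([[iv.start], cuts, [iv.end]])
            for f in range(n_frag):
                s = int(bounds[f])
                e = int(bounds[f + 1])
                # extend into the neighbour fragment to create overlap,
                # never past the locus boundary
                s = max(iv.start, s - int(rng.integers(0, 30)))
                e = min(iv.end, e + int(rng.integers(0, 30)))
                fragments.append((GenomicInterval(iv.contig_id, s, e), locus_id))
            # expressed loci also show read depth, irrelevant for novelty
            coverage[iv.contig_id][iv.start : iv.end] = np.maximum(
                coverage[iv.contig_id][iv.start : iv.end],
                rng.poisson(20, size=iv.length),
            )

    from .model import Locus, LocusSource

    truth = LocusSet(
        [
            Locus(
                tid,
                iv,
                LocusSource.coverage_derived
                if i in coverage_only
                else LocusSource.transcript_derived,
            )
            for i, (tid, iv) in enumerate(zip(truth_ids, truth_intervals))
        ]
    )
    return fragments, coverage, truth


def simulate_term_map(
    truth: TruthLabels,
    seed: int = 0,
    n_background_terms: int = 20,
    frac_annotated: float = 0.6,
):
    """A synthetic gene-to-term annotation map with one planted signal.

    Background terms annotate random loci; one extra term
    ("TERM:senescence") preferentially annotates planted senescence-DE
    loci, so enrichment reports on synthetic runs contain a true positive.
    Returns a :class:`wheatsen.enrichment.TermMap`.
    """
    from .enrichment import TermMap

    rng = np.random.default_rng(seed + 7)
    locus_ids = np.asarray(truth.table.index)
    n = len(locus_ids)
    annotated = locus_ids[rng.random(n) < frac_annotated]
    term_to_loci: dict[str, set[str]] = {}
    for t in range(n_background_terms):
        size = int(rng.integers(5, max(6, n // 10)))
        term_to_loci[f"TERM:{t:04d}"] = set(
            rng.choice(annotated, size=min(size, len(annotated)), replace=False)
        )
    de = np.asarray(sorted(truth.de_ids() & set(annotated)))
    non_de = np.asarray(sorted(set(annotated) - truth.de_ids()))
    planted = set()
    if len(de):
        planted |= set(rng.choice(de, size=max(1, len(de) // 2), replace=False))
    if len(non_de):
        planted |= set(rng.choice(non_de, size=max(1, len(non_de) // 20), replace=False))
    term_to_loci["TERM:senescence"] = planted
    labels = {t: f"synthetic term {t}" for t in term_to_loci}
    labels["TERM:senescence"] = "synthetic senescence-regulated module"
    return TermMap(term_to_loci, labels)
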