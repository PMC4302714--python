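#!/usr/bin/env python
"""Generate the synthetic experiment: counts with planted truth, plus
transcript fragments and coverage tracks for the annotation stage.

Writes everything under results/data/.  The design mirrors the field
experiment: 3 genotypes (WT, gpc-A1, gpc-A1/gpc-B2) x 3 time points
(HD, 12 DAA, 22 DAA) x 4 replicates, 2,000 loci, 30% senescence-DE with
|log2FC| = 2 per transition, and GPC1/GPC2/redundant regulator labels
planted on 15/10/20% of the DE loci.
"""

from pathlib import Path

from wheatsen.io import (
    write_bed_intervals,
    write_count_table,
    write_coverage,
    write_gff,
    write_sample_sheet,
)
from wheatsen.simulate import (
    SimulationConfig,
    simulate_annotation_inputs,
    simulate_counts,
    simulate_term_map,
)

SEED = 20260924
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)

    cm, truth = simulate_counts(cfg)
    write_count_table(cm, OUT / "raw_counts.tsv")
    write_sample_sheet(cm.samples, OUT / "sample_sheet.tsv")
    truth.table.to_csv(OUT / "truth_labels.tsv", sep="\t")

    fragments, coverage, truth_loci = simulate_annotation_inputs(cfg)
    write_bed_intervals([iv for iv, _ in fragments], OUT / "transcript_fragments.bed")
    write_coverage(coverage, OUT / "coverage.tsv")
    write_gff(truth_loci, OUT / "truth_loci.gff3")

    tm = simulate_term_map(truth, seed=SEED)
    with open(OUT / "term_map.tsv", "w") as fh:
        for term, loci in sorted(tm.term_to_loci.items()):
            for locus in sorted(loci):
                fh.write(f"{locus}\t{term}\n")
    with open(OUT / "term_labels.tsv", "w") as fh:
        for term, label in sorted(tm.labels.items()):
            fh.write(f"{term}\t{label}\n")

    n_de = int(truth.table.is_senescence_de.sum())
    print(f"simulated {cfg.n_loci} loci x {cm.n_samples} samples (seed {SEED})")
    print(f"planted senescence-DE loci: {n_de}")
    print(truth.table.regulator.value_counts().to_string())
    print(f"annotation truth loci: {len(truth_loci)} "
          f"({cfg.n_coverage_only} discoverable only from coverage)")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
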