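#!/usr/bin/env python
"""Run the twelve pairwise comparisons with the four-test consensus.

Three WT time-course comparisons plus the three genotype pairs at each
time point.  Each comparison writes a per-locus table (four p-values,
BH-adjusted q for the two count-model tests, log2 fold change,
direction, consensus call) under results/comparisons/, and the
genotype-level union DE sets are saved for the set-algebra stage.
"""

import json
from pathlib import Path

from wheatsen.diffexpr import run_all_comparisons
from wheatsen.io import load_count_table
from wheatsen.model import Thresholds

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cm = load_count_table(ROOT / "filtered_counts.tsv", ROOT / "data" / "sample_sheet.tsv")
    results = run_all_comparisons(cm, Thresholds())

    comp_dir = ROOT / "comparisons"
    comp_dir.mkdir(parents=True, exist_ok=True)
    for label, result in results.results.items():
        path = comp_dir / f"{label.replace(':', '__')}.tsv"
        result.table.rename_axis("locus_id").to_csv(path, sep="\t")
        print(f"{label}: {int(result.table.is_de.sum())} DE loci")

    with open(ROOT / "genotype_sets.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in results.genotype_sets.items()}, fh, indent=2)
    print(f"senescence-DE union: {len(results.senescence_de_ids)} loci")
    print(f"comparison tables -> {comp_dir}")


if __name__ == "__main__":
    main()
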