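#!/usr/bin/env python
"""Arrow-style report for a panel of genes of interest.

Builds a small synthetic family panel (planted GPC1-regulated loci plus
unregulated controls, labelled like transporter families) and reports
normalized WT means per time point with up/down arrows for the
senescence and genotype comparisons.
"""

from pathlib import Path

import pandas as pd

from wheatsen.diffexpr import ComparisonResult, run_all_comparisons
from wheatsen.io import load_count_table
from wheatsen.model import Thresholds
from wheatsen.report import family_report

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_results(cm):
    from wheatsen.diffexpr import AllComparisons, comparison_plan, GENOTYPE_PAIRS
    from wheatsen.model import TIMEPOINT_ORDER

    results = {}
    for spec in comparison_plan(cm):
        path = ROOT / "comparisons" / f"{spec.label.replace(':', '__')}.tsv"
        results[spec.label] = ComparisonResult(
            spec.label, pd.read_csv(path, sep="\t", index_col="locus_id")
        )
    genotype_sets = {}
    for pair_label, _a, _b in GENOTYPE_PAIRS:
        union = set()
        for tp in TIMEPOINT_ORDER:
            union |= results[f"{tp.value}:{pair_label}"].de_ids
        genotype_sets[pair_label] = union
    return AllComparisons(results, genotype_sets)


def main() -> None:
    cm = load_count_table(ROOT / "filtered_counts.tsv", ROOT / "data" / "sample_sheet.tsv")
    results = load_results(cm)
    truth = pd.read_csv(ROOT / "data" / "truth_labels.tsv", sep="\t", index_col=0)

    gpc1 = truth.index[truth.regulator == "GPC1"][:6]
    controls = truth.index[(truth.regulator == "none") & ~truth.is_senescence_de][:4]
    fam = pd.DataFrame(
        {
            "gene_id": [f"PANEL{i}" for i in range(len(gpc1) + len(controls))],
            "family": ["ZIP"] * len(gpc1) + ["control"] * len(controls),
            "locus_id": list(gpc1) + list(controls),
        }
    )
    report = family_report(cm, results, fam)
    report.to_csv(ROOT / "family_report.tsv", sep="\t", index=False)
    print(report.to_string(index=False, float_format=lambda v: f"{v:.0f}"))
    print(f"\nreport -> {ROOT / 'family_report.tsv'}")


if __name__ == "__main__":
    main()
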