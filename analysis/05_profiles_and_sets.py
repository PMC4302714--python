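#!/usr/bin/env python
"""Classify senescence-DE loci into the eight temporal profile classes
and compute the genotype set algebra, then score both against the
planted truth.

Profile classes combine the HD->12 DAA and 12->22 DAA transitions
(Up/Down/Flat, excluding Flat-Flat; endpoint-only loci fold into Up-Up /
Down-Down).  High-confidence GPC-regulated sets are intersections of a
single-mutant comparison with the double-mutant comparison.
"""

import json
from pathlib import Path

import pandas as pd

from wheatsen.diffexpr import ComparisonResult
from wheatsen.gene_sets import (
    high_confidence_sets,
    overlap_fraction,
    redundancy_fraction,
    tally_directions,
)
from wheatsen.profiles import class_fractions, classify_profiles, profile_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_result(label: str) -> ComparisonResult:
    path = ROOT / "comparisons" / f"{label.replace(':', '__')}.tsv"
    return ComparisonResult(label, pd.read_csv(path, sep="\t", index_col="locus_id"))


def main() -> None:
    r_hd12 = load_result("WT:HD_vs_12DAA")
    r_hd22 = load_result("WT:HD_vs_22DAA")
    r_1222 = load_result("WT:12DAA_vs_22DAA")

    assigns = classify_profiles(r_hd12, r_1222, r_hd22)
    profile_table(assigns).to_csv(ROOT / "profile_assignments.tsv", sep="\t")
    cf = class_fractions(assigns)
    cf.rename_axis("profile_class").to_csv(ROOT / "profile_class_fractions.tsv", sep="\t")
    print("profile classes over", len(assigns), "senescence-DE loci:")
    print(cf.round(1).to_string())

    for r in (r_hd12, r_1222):
        n_up, n_down, pct_up, pct_down = tally_directions(r)
        print(f"{r.label}: {n_up} up ({pct_up:.1f}%), {n_down} down ({pct_down:.1f}%)")

    genotype_sets = {
        k: set(v) for k, v in json.loads((ROOT / "genotype_sets.json").read_text()).items()
    }
    rep = high_confidence_sets(genotype_sets)
    sen = {a.locus_id for a in assigns}
    n1, pct1 = overlap_fraction(rep.hc_gpc1, sen)
    n2, pct2 = overlap_fraction(rep.hc_gpc2, sen)
    cells = rep.venn_cells()
    redundancy = redundancy_fraction(
        cells["D_only"], cells["A_and_B_and_D"],
        cells["A_only"] + cells["A_and_D_only"],
        cells["B_only"] + cells["B_and_D_only"],
    )
    summary = {
        "counts": rep.counts(),
        "venn_cells": cells,
        "hc_gpc1_senescence_overlap": {"n": n1, "pct": round(pct1, 1)},
        "hc_gpc2_senescence_overlap": {"n": n2, "pct": round(pct2, 1)},
        "redundancy_pct": round(redundancy, 1),
    }
    (ROOT / "set_report.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))

    # score against planted truth
    truth = pd.read_csv(ROOT / "data" / "truth_labels.tsv", sep="\t", index_col=0)
    planted = truth.loc[truth.is_senescence_de, "profile_class"]
    assigned = profile_table(assigns)["profile_class"].reindex(planted.index)
    print(f"profile-class recovery vs truth: {(assigned == planted).mean():.3f}")
    for reg, target in (("GPC1", rep.hc_gpc1), ("GPC2", rep.hc_gpc2),
                        ("redundant", rep.double_only | rep.triple)):
        ids = set(truth.index[truth.regulator == reg])
        print(f"{reg} recovery into its cell: {len(ids & target) / max(len(ids), 1):.3f}")


if __name__ == "__main__":
    main()
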