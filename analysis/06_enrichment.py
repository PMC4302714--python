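#!/usr/bin/env python
"""Classic Fisher term enrichment of the up- and downregulated
senescence sets and the high-confidence GPC sets.

The synthetic term map plants one term over senescence-DE loci, so the
top row of the senescence reports should be that term at a small p.
"""

import json
from pathlib import Path

import pandas as pd

from wheatsen.enrichment import TermMap, fisher_enrichment

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tm = TermMap.from_tsv(ROOT / "data" / "term_map.tsv", ROOT / "data" / "term_labels.tsv")
    universe = set(
        pd.read_csv(ROOT / "filtered_counts.tsv", sep="\t", index_col=0).index
    )
    profiles = pd.read_csv(ROOT / "profile_assignments.tsv", sep="\t", index_col=0)
    up = set(profiles.index[profiles.profile_class.str.startswith("Up")])
    down = set(profiles.index[profiles.profile_class.str.startswith("Down")])
    genotype_sets = json.loads((ROOT / "genotype_sets.json").read_text())
    hc_gpc1 = set(genotype_sets["WT_vs_gpcA1"]) & set(genotype_sets["WT_vs_gpcA1_gpcB2"])

    for name, gene_set in (("senescence_up", up), ("senescence_down", down),
                           ("hc_gpc1", hc_gpc1)):
        query = gene_set & tm.annotated_universe() & universe
        if not query:
            print(f"{name}: no annotated loci, skipped")
            continue
        table = fisher_enrichment(query, universe, tm)
        table.to_csv(ROOT / f"enrichment_{name}.tsv", sep="\t", index=False)
        top = table.iloc[0]
        print(f"{name}: {len(query)} annotated loci; top term {top.term_id} "
              f"({top.label}): annotated={top.annotated} significant={top.significant} "
              f"expected={top.expected:.1f} p={top.p:.3g}")


if __name__ == "__main__":
    main()
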