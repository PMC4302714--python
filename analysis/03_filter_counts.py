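#!/usr/bin/env python
"""Load the raw count table, apply the low-count retention rule, and
estimate size factors.

A locus is kept only if some genotype/time-point cell has more than
three reads in at least two replicates.  Size factors are
median-of-ratios over the retained matrix.
"""

from pathlib import Path

import pandas as pd

from wheatsen.counting import low_count_filter
from wheatsen.diffexpr import size_factors
from wheatsen.io import load_count_table, write_count_table
from wheatsen.model import Thresholds

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cm = load_count_table(ROOT / "data" / "raw_counts.tsv", ROOT / "data" / "sample_sheet.tsv")
    retained, removed = low_count_filter(cm, Thresholds())
    write_count_table(retained, ROOT / "filtered_counts.tsv")
    pd.Series(removed, name="locus_id").to_csv(ROOT / "removed_loci.tsv", sep="\t", index=False)

    factors = size_factors(retained, allow_positive_fallback=True)
    pd.DataFrame(
        {"sample_id": [s.sample_id for s in retained.samples], "size_factor": factors}
    ).to_csv(ROOT / "size_factors.tsv", sep="\t", index=False)

    print(f"{cm.n_loci} loci in, {retained.n_loci} retained, {len(removed)} removed")
    print(f"size factors span {factors.min():.3f} .. {factors.max():.3f}")
    print(f"filtered counts -> {ROOT / 'filtered_counts.tsv'}")


if __name__ == "__main__":
    main()
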