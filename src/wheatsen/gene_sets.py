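"""Set algebra over the genotype-level DE sets.

Three genotype-level DE sets enter: WT vs gpc-A1 (dominated by
GPC-A1-regulated loci), WT vs gpc-A1/gpc-B2 (loci regulated by either
gene), and gpc-A1 vs gpc-A1/gpc-B2 (dominated by GPC-B2-regulated loci).
High-confidence regulated sets are intersections with the double-mutant
comparison; loci DE only against the double mutant, together with loci
DE in all three comparisons, constitute the redundancy evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

#: Keys expected in the genotype_sets mapping.
SET_GPC1 = "WT_vs_gpcA1"
SET_DOUBLE = "WT_vs_gpcA1_gpcB2"
SET_GPC2 = "gpcA1_vs_gpcA1_gpcB2"


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used for reported percentages."""
    import decimal

    d = decimal.Decimal(repr(x)).quantize(
        decimal.Decimal("1." + "0" * ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


@dataclass
class GeneSetReport:
    """Named sets, Venn cells, and derived counts of the genotype algebra."""

    gpc1_wt_vs_a1: set[str]
    gpc_double_wt_vs_ab: set[str]
    gpc2_a1_vs_ab: set[str]
    hc_gpc1: set[str] = field(init=False)
    hc_gpc2: set[str] = field(init=False)
    triple: set[str] = field(init=False)
    double_only: set[str] = field(init=False)
    singles_overlap: set[str] = field(init=False)

    def __post_init__(self) -> None:
        a, d, b = self.gpc1_wt_vs_a1, self.gpc_double_wt_vs_ab, self.gpc2_a1_vs_ab
        self.hc_gpc1 = a & d
        self.hc_gpc2 = b & d
        self.triple = a & d & b
        self.double_only = d - a - b
        self.singles_overlap = a & b

    def venn_cells(self) -> dict[str, int]:
        """All seven Venn cells of the three genotype-level sets."""
        a, d, b = self.gpc1_wt_vs_a1, self.gpc_double_wt_vs_ab, self.gpc2_a1_vs_ab
        return {
            "A_only": len(a - d - b),
            "D_only": len(d - a - b),
            "B_only": len(b - a - d),
            "A_and_D_only": len((a & d) - b),
            "B_and_D_only": len((b & d) - a),
            "A_and_B_only": len((a & b) - d),
            "A_and_B_and_D": len(a & b & d),
        }

    def counts(self) -> dict[str, int]:
        return {
            "gpc1_wt_vs_a1": len(self.gpc1_wt_vs_a1),
            "gpc_double_wt_vs_ab": len(self.gpc_double_wt_vs_ab),
            "gpc2_a1_vs_ab": len(self.gpc2_a1_vs_ab),
            "hc_gpc1": len(self.hc_gpc1),
            "hc_gpc2": len(self.hc_gpc2),
            "triple": len(self.triple),
            "double_only": len(self.double_only),
        }


def high_confidence_sets(genotype_sets: Mapping[str, set[str]]) -> GeneSetReport:
    """Build the gene-set report from the three genotype-level DE sets."""
    missing = {SET_GPC1, SET_DOUBLE, SET_GPC2} - set(genotype_sets)
    if missing:
        raise ValueError(f"missing genotype-level sets: {sorted(missing)}")
    return GeneSetReport(
        set(genotype_sets[SET_GPC1]),
        set(genotype_sets[SET_DOUBLE]),
        set(genotype_sets[SET_GPC2]),
    )


def tally_directions(result) -> tuple[int, int, float, float]:
    """Up/down counts and percentages among DE loci of one comparison.

    Returns (n_up, n_down, pct_up, pct_down); percentages are NaN when no
    locus is DE.
    """
    de = result.table[result.table["is_de"]]
    n_up = int((de["direction"] == "up").sum())
    n_down = int((de["direction"] == "down").sum())
    total = n_up + n_down
    if total == 0:
        return 0, 0, float("nan"), float("nan")
    return n_up, n_down, 100 * n_up / total, 100 * n_down / total


def overlap_fraction(set_a: set, set_b: set) -> tuple[int, float]:
    """|A n B| and its percentage of |A| (NaN for empty A)."""
    n = len(set_a & set_b)
    if not set_a:
        return n, float("nan")
    return n, 100 * n / len(set_a)


def redundancy_fraction(
    double_only: int, triple: int, gpc1_only: int, gpc2_only: int
) -> float:
    """Percentage of regulated loci with evidence of redundant regulation.

    Redundancy evidence = loci DE only against the double mutant plus loci
    DE in all three comparisons, over the union of the four exclusive
    categories.  NaN when the union is empty.
    """
    if min(double_only, triple, gpc1_only, gpc2_only) < 0:
        raise ValueError("counts must be non-negative")
    total = double_only + triple + gpc1_only + gpc2_only
    if total == 0:
        return float("nan")
    return 100 * (double_only + triple) / total
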