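"""Arrow-style family report over genes of interest.

For each gene mapped to a locus, the report carries the normalized mean
count at the three WT time points and an arrow per comparison: for the
senescence column an up/down arrow when the locus is DE over the WT time
course, and for each genotype comparison an arrow when the locus is DE,
pointing up when expression is higher in WT (our comparisons compute
log2fc of mutant over WT, so "higher in WT" is direction == "down").
"""

from __future__ import annotations

import logging
import os
import numpy as np
import pandas as pd

from .diffexpr import AllComparisons, WT_TIME_LABELS, size_factors
from .model import CountMatrix, Genotype, TIMEPOINT_ORDER

logger = logging.getLogger(__name__)

UP_ARROW = "⬆"
DOWN_ARROW = "⬇"


def read_family_map(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with columns gene_id, family, locus_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "family", "locus_id"} - set(df.columns)
    if missing:
        raise ValueError(f"family map missing columns: {sorted(missing)}")
    return df


def _senescence_arrow(all_results: AllComparisons, locus_id: str) -> str:
    """Arrow for the time course: direction of the earliest significant step."""
    for label in WT_TIME_LABELS:
        row = all_results.results[label].table.loc[locus_id]
        if row["is_de"]:
            return UP_ARROW if row["direction"] == "up" else DOWN_ARROW
    return ""


def _genotype_arrow(all_results: AllComparisons, pair_label: str, locus_id: str) -> str:
    """Arrow when DE in any time point of the pair; up = higher in WT."""
    for tp in TIMEPOINT_ORDER:
        row = all_results.results[f"{tp.value}:{pair_label}"].table.loc[locus_id]
        if row["is_de"]:
            return DOWN_ARROW if row["direction"] == "up" else UP_ARROW
    return ""


def family_report(
    cm: CountMatrix,
    all_results: AllComparisons,
    family_map: pd.DataFrame,
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene normalized WT means and DE arrows.

    Genes whose locus is absent from the count universe are reported with
    empty cells and logged, never fatal.
    """
    if factors is None:
        factors = size_factors(cm, allow_positive_fallback=True)
    norm = cm.counts / factors
    wt_cols = {
        tp: [cm.samples[j].sample_id for j in cm.columns_for(Genotype.WT, tp)]
        for tp in TIMEPOINT_ORDER
    }
    rows = []
    for rec in family_map.itertuples(index=False):
        locus_id = rec.locus_id
        row: dict[str, object] = {
            "gene_id": rec.gene_id,
            "family": rec.family,
            "locus_id": locus_id,
        }
        if locus_id not in cm.counts.index:
            logger.warning("family map locus %s absent from count universe", locus_id)
            for tp in TIMEPOINT_ORDER:
                row[f"WT_{tp.value}_mean"] = np.nan
            row["senescence"] = ""
            row["WT_vs_gpcA1"] = ""
            row["WT_vs_gpcA1_gpcB2"] = ""
        else:
            for tp in TIMEPOINT_ORDER:
                row[f"WT_{tp.value}_mean"] = float(norm.loc[locus_id, wt_cols[tp]].mean())
            row["senescence"] = _senescence_arrow(all_results, locus_id)
            row["WT_vs_gpcA1"] = _genotype_arrow(all_results, "WT_vs_gpcA1", locus_id)
            row["WT_vs_gpcA1_gpcB2"] = _genotype_arrow(
                all_results, "WT_vs_gpcA1_gpcB2", locus_id
            )
        rows.append(row)
    return pd.DataFrame(rows)
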