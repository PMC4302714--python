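"""Classic Fisher over-representation analysis of a gene set.

Every term is tested independently with a one-sided hypergeometric test
of the 2x2 table (in query / annotated to term against the annotated
universe).  No ontology-graph weighting or elimination is applied, and
no multiple-testing correction: the report carries raw p-values in the
Annotated / Significant / Expected / P schema.  Ancestor propagation, if
wanted, must be precomputed into the term map.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats


@dataclass
class TermMap:
    """Mapping of terms to annotated loci, with optional labels."""

    term_to_loci: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def annotated_universe(self) -> set[str]:
        out: set[str] = set()
        for loci in self.term_to_loci.values():
            out |= loci
        return out

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, labels_path: str | os.PathLike | None = None) -> "TermMap":
        """Two-column TSV (locus_id, term_id); labels TSV (term_id, label)."""
        df = pd.read_csv(path, sep="\t", names=["locus_id", "term_id"], comment="#", dtype=str)
        term_to_loci: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            term_to_loci.setdefault(row.term_id, set()).add(row.locus_id)
        labels: dict[str, str] = {}
        if labels_path is not None:
            ldf = pd.read_csv(labels_path, sep="\t", names=["term_id", "label"], comment="#", dtype=str)
            labels = dict(zip(ldf["term_id"], ldf["label"]))
        return cls(term_to_loci, labels)


def fisher_enrichment(
    query: Iterable[str], universe: Iterable[str], tm: TermMap
) -> pd.DataFrame:
    """Per-term over-representation p-values for a query gene set.

    The universe is restricted to annotated loci; the query must be a
    subset of the universe.  Output columns mirror the standard report:
    term_id, label, annotated (in universe), significant (in query),
    expected (annotated * |query| / |universe|), p (one-sided
    hypergeometric upper tail).  Rows are sorted by p with term_id as the
    tie-break.
    """
    query = set(query)
    universe = set(universe) & tm.annotated_universe()
    if not universe:
        raise ValueError("empty annotated universe")
    query &= universe
    if not query:
        raise ValueError("query has no annotated loci in the universe")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for term_id, loci in tm.term_to_loci.items():
        annotated = loci & universe
        k_ann = len(annotated)
        if k_ann == 0:
            continue
        k_sig = len(annotated & query)
        expected = k_ann * n_query / n_universe
        # P(X >= k_sig), X ~ Hypergeom(N=n_universe, K=k_ann, n=n_query)
        p = float(stats.hypergeom.sf(k_sig - 1, n_universe, k_ann, n_query))
        rows.append(
            {
                "term_id": term_id,
                "label": tm.labels.get(term_id, ""),
                "annotated": k_ann,
                "significant": k_sig,
                "expected": expected,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows, columns=["term_id", "label", "annotated", "significant", "expected", "p"])
    return df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
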