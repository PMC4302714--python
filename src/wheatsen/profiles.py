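"""Temporal profile classes for senescence-regulated loci.

Each locus differentially expressed in at least one of the three WT
time-course comparisons is assigned one of eight classes built from its
two transitions (HD -> 12 DAA and 12 DAA -> 22 DAA): Up, Down, or Flat
per transition, excluding Flat-Flat.  A locus flat in both transitions
but significant between HD and 22 DAA is folded into Up-Up or Down-Down
according to its overall direction; that fold-in rule applies only to
Flat-Flat loci — a locus significant in both transitions keeps the class
its transitions define even if the endpoint comparison is not
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: The eight admissible (transition1, transition2) combinations.
PROFILE_CLASSES = (
    "Up-Up",
    "Up-Flat",
    "Up-Down",
    "Flat-Up",
    "Flat-Down",
    "Down-Up",
    "Down-Flat",
    "Down-Down",
)


@dataclass(frozen=True)
class ProfileAssignment:
    locus_id: str
    profile_class: str
    basis: str  # which comparisons drove the call


def _transition(result_row) -> str:
    if not result_row["is_de"]:
        return "Flat"
    return "Up" if result_row["direction"] == "up" else "Down"


def classify_profiles(r_hd12, r_1222, r_hd22) -> list[ProfileAssignment]:
    """Assign one profile class to every senescence-DE locus.

    The three arguments are the ComparisonResults of HD vs 12 DAA,
    12 DAA vs 22 DAA, and HD vs 22 DAA, computed on the same locus
    universe.  Loci flat everywhere receive no assignment; every locus DE
    in at least one of the three comparisons receives exactly one class.
    """
    t12, t22, t02 = r_hd12.table, r_1222.table, r_hd22.table
    if not (t12.index.equals(t22.index) and t12.index.equals(t02.index)):
        raise ValueError("comparison results cover different locus universes")
    out: list[ProfileAssignment] = []
    for locus_id in t12.index:
        row12 = t12.loc[locus_id]
        row22 = t22.loc[locus_id]
        row02 = t02.loc[locus_id]
        tr1 = _transition(row12)
        tr2 = _transition(row22)
        if tr1 == "Flat" and tr2 == "Flat":
            if not row02["is_de"]:
                continue  # flat everywhere: not senescence-DE
            cls = "Up-Up" if row02["direction"] == "up" else "Down-Down"
            out.append(ProfileAssignment(locus_id, cls, "HD_vs_22DAA fold-in"))
        else:
            out.append(ProfileAssignment(locus_id, f"{tr1}-{tr2}", "transitions"))
    return out


def profile_table(assignments: list[ProfileAssignment]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "locus_id": [a.locus_id for a in assignments],
            "profile_class": [a.profile_class for a in assignments],
            "basis": [a.basis for a in assignments],
        }
    )
    return df.set_index("locus_id")


def class_fractions(assignments: list[ProfileAssignment]) -> pd.DataFrame:
    """Counts and percentages per class over all assigned loci."""
    df = profile_table(assignments)
    counts = df["profile_class"].value_counts().reindex(PROFILE_CLASSES, fill_value=0)
    total = int(counts.sum())
    pct = counts / total * 100 if total else counts * float("nan")
    return pd.DataFrame({"n": counts, "percent": pct})
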