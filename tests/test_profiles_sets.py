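"""Profile classification and the genotype set algebra."""

import numpy as np
import pandas as pd
import pytest

from wheatsen.diffexpr import ComparisonResult
from wheatsen.gene_sets import (
    GeneSetReport,
    high_confidence_sets,
    overlap_fraction,
    redundancy_fraction,
    round_half_away,
    tally_directions,
)
from wheatsen.profiles import (
    PROFILE_CLASSES,
    class_fractions,
    classify_profiles,
    profile_table,
)


def fake_result(label, calls):
    """Build a ComparisonResult from {locus: (is_de, direction)}."""
    idx = list(calls)
    table = pd.DataFrame(
        {
            "is_de": [calls[k][0] for k in idx],
            "direction": [calls[k][1] for k in idx],
            "log2fc": [1.0 if calls[k][1] == "up" else -1.0 for k in idx],
        },
        index=idx,
    )
    return ComparisonResult(label, table)


class TestClassifyProfiles:
    def _three(self, spec):
        """spec: {locus: ((de12, dir12), (de22, dir22), (de02, dir02))}."""
        r12 = fake_result("hd12", {k: v[0] for k, v in spec.items()})
        r22 = fake_result("1222", {k: v[1] for k, v in spec.items()})
        r02 = fake_result("hd22", {k: v[2] for k, v in spec.items()})
        return r12, r22, r02

    def test_transition_combinations(self):
        spec = {
            "updown": ((True, "up"), (True, "down"), (False, "up")),
            "upflat": ((True, "up"), (False, "up"), (True, "up")),
            "flatdown": ((False, "up"), (True, "down"), (True, "down")),
            "downdown": ((True, "down"), (True, "down"), (True, "down")),
        }
        got = {
            a.locus_id: a.profile_class
            for a in classify_profiles(*self._three(spec))
        }
        assert got == {
            "updown": "Up-Down",
            "upflat": "Up-Flat",
            "flatdown": "Flat-Down",
            "downdown": "Down-Down",
        }

    def test_flat_flat_fold_in_rule(self):
        """Loci flat in both transitions but DE endpoint-to-endpoint are
        folded into Up-Up or Down-Down; flat everywhere stays unassigned."""
        spec = {
            "lateup": ((False, "up"), (False, "up"), (True, "up")),
            "latedown": ((False, "up"), (False, "up"), (True, "down")),
            "never": ((False, "up"), (False, "up"), (False, "up")),
        }
        got = {a.locus_id: a for a in classify_profiles(*self._three(spec))}
        assert got["lateup"].profile_class == "Up-Up"
        assert got["lateup"].basis == "HD_vs_22DAA fold-in"
        assert got["latedown"].profile_class == "Down-Down"
        assert "never" not in got

    def test_fold_in_never_overrides_transitions(self):
        """Both transitions significant but the endpoint flat: the class
        still comes from the transitions (the fold-in only rescues
        Flat-Flat loci)."""
        spec = {"x": ((True, "up"), (True, "down"), (False, "up"))}
        (a,) = classify_profiles(*self._three(spec))
        assert a.profile_class == "Up-Down"

    def test_partition_property(self):
        """Every senescence-DE locus gets exactly one class; others none."""
        rng = np.random.default_rng(0)
        spec = {}
        for i in range(300):
            spec[f"L{i}"] = tuple(
                (bool(rng.random() < 0.4), "up" if rng.random() < 0.5 else "down")
                for _ in range(3)
            )
        r12, r22, r02 = self._three(spec)
        assigns = classify_profiles(r12, r22, r02)
        assigned = [a.locus_id for a in assigns]
        assert len(assigned) == len(set(assigned))
        de_any = {
            k for k, v in spec.items() if v[0][0] or v[1][0] or v[2][0]
        }
        assert set(assigned) == de_any
        assert all(a.profile_class in PROFILE_CLASSES for a in assigns)

    def test_mismatched_universes_rejected(self):
        r12 = fake_result("a", {"L1": (True, "up")})
        r22 = fake_result("b", {"L2": (True, "up")})
        with pytest.raises(ValueError, match="universe"):
            classify_profiles(r12, r22, r12)

    def test_class_fractions_sum_to_100(self):
        spec = {
            f"L{i}": ((True, "up"), (False, "up"), (False, "up")) for i in range(3)
        }
        spec["L3"] = ((True, "down"), (True, "down"), (True, "down"))
        assigns = classify_profiles(*self._three(spec))
        cf = class_fractions(assigns)
        assert cf["n"].sum() == 4
        assert cf["percent"].sum() == pytest.approx(100.0)
        assert cf.loc["Up-Flat", "n"] == 3


class TestTallyDirections:
    def test_study_arithmetic(self):
        """1,298 of 1,703 DE loci up corresponds to 76.2% up / 23.8% down."""
        calls = {f"u{i}": (True, "up") for i in range(1298)}
        calls.update({f"d{i}": (True, "down") for i in range(405)})
        calls["nd"] = (False, "up")
        n_up, n_down, pct_up, pct_down = tally_directions(fake_result("x", calls))
        assert (n_up, n_down) == (1298, 405)
        assert round_half_away(pct_up) == 76.2
        assert round_half_away(pct_down) == 23.8

    def test_no_de_gives_nan(self):
        n_up, n_down, pct_up, _ = tally_directions(
            fake_result("x", {"a": (False, "up")})
        )
        assert (n_up, n_down) == (0, 0) and np.isnan(pct_up)

    def test_conservation(self, rng):
        calls = {
            f"L{i}": (bool(rng.random() < 0.5), "up" if rng.random() < 0.5 else "down")
            for i in range(200)
        }
        n_up, n_down, *_ = tally_directions(fake_result("x", calls))
        assert n_up + n_down == sum(1 for v in calls.values() if v[0])


class TestHighConfidenceSets:
    def test_hand_example(self):
        rep = high_confidence_sets(
            {
                "WT_vs_gpcA1": {1, 2, 3},
                "WT_vs_gpcA1_gpcB2": {2, 3, 4},
                "gpcA1_vs_gpcA1_gpcB2": {3, 5},
            }
        )
        assert rep.hc_gpc1 == {2, 3}
        assert rep.hc_gpc2 == {3}
        assert rep.triple == {3}
        assert rep.double_only == {4}

    def test_disjoint_sets_empty_intersections(self):
        rep = high_confidence_sets(
            {
                "WT_vs_gpcA1": {1},
                "WT_vs_gpcA1_gpcB2": {2},
                "gpcA1_vs_gpcA1_gpcB2": {3},
            }
        )
        assert not rep.hc_gpc1 and not rep.hc_gpc2 and not rep.triple
        assert rep.double_only == {2}

    def test_venn_cells_partition_union(self, rng):
        universe = list(range(200))
        sets = {
            k: set(rng.choice(universe, size=60, replace=False))
            for k in ("WT_vs_gpcA1", "WT_vs_gpcA1_gpcB2", "gpcA1_vs_gpcA1_gpcB2")
        }
        rep = high_confidence_sets(sets)
        cells = rep.venn_cells()
        union = sets["WT_vs_gpcA1"] | sets["WT_vs_gpcA1_gpcB2"] | sets["gpcA1_vs_gpcA1_gpcB2"]
        assert sum(cells.values()) == len(union)

    def test_missing_set_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            high_confidence_sets({"WT_vs_gpcA1": set()})


class TestOverlapAndRedundancy:
    @pytest.mark.parametrize(
        "n_inter,n_a,expected",
        [(206, 321, 64.2), (83, 224, 37.1)],
    )
    def test_study_overlap_arithmetic(self, n_inter, n_a, expected):
        a = set(range(n_a))
        b = set(range(n_inter)) | {10_000 + i for i in range(50)}
        n, frac = overlap_fraction(a, b)
        assert n == n_inter
        assert round_half_away(frac) == expected

    def test_subset_is_full_overlap(self):
        n, frac = overlap_fraction({1, 2}, {1, 2, 3})
        assert n == 2 and frac == 100.0

    def test_empty_a_is_nan(self):
        _, frac = overlap_fraction(set(), {1})
        assert np.isnan(frac)

    def test_study_redundancy_arithmetic(self):
        assert round_half_away(redundancy_fraction(1349, 31, 489, 261)) == 64.8

    def test_no_redundant_loci(self):
        assert redundancy_fraction(0, 0, 10, 10) == 0.0

    def test_consistent_with_explicit_sets(self, rng):
        d, t, g1, g2 = (int(x) for x in rng.integers(0, 50, 4))
        if d + t + g1 + g2 == 0:
            d = 1
        # build literal disjoint sets with those cardinalities
        ids = iter(range(10_000))
        cells = {k: {next(ids) for _ in range(n)} for k, n in
                 (("d", d), ("t", t), ("g1", g1), ("g2", g2))}
        frac = redundancy_fraction(d, t, g1, g2)
        explicit = 100 * len(cells["d"] | cells["t"]) / len(
            cells["d"] | cells["t"] | cells["g1"] | cells["g2"]
        )
        assert frac == pytest.approx(explicit)
        assert 0 <= frac <= 100
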