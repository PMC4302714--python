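"""Normalization, the four tests, and the consensus DE call."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from wheatsen.diffexpr import (
    ComparisonSpec,
    DispersionTrend,
    bh_adjust,
    comparison_plan,
    conditional_exact_p,
    mww_test,
    nb_exact_test,
    run_all_comparisons,
    run_comparison,
    size_factors,
    t_test,
)
from wheatsen.model import Thresholds
from wheatsen.simulate import SimulationConfig, simulate_counts
from .conftest import make_count_matrix


# ---------------------------------------------------------------------------
# Independent oracles


def oracle_conditional_p(k_a, total, n_a, n_b, mu0, alpha, tie_tol=1e-7):
    """Direct enumeration of the conditional split distribution.

    Uses its own lgamma-based NB pmf and plain float sums, independent of
    the implementation's scipy/logsumexp path.
    """

    def logpmf(k, n):
        m = n * mu0
        if alpha == 0:
            return k * math.log(m) - m - math.lgamma(k + 1) if m > 0 else (0.0 if k == 0 else -math.inf)
        r = n / alpha
        p = r / (r + m)
        return (
            math.lgamma(k + r)
            - math.lgamma(r)
            - math.lgamma(k + 1)
            + r * math.log(p)
            + k * math.log1p(-p)
        )

    weights = [math.exp(logpmf(k, n_a) + logpmf(total - k, n_b)) for k in range(total + 1)]
    z = sum(weights)
    obs = weights[k_a]
    return sum(w for w in weights if w <= obs * (1 + tie_tol)) / z


def oracle_bh(p):
    """Textbook step-up BH: sort, scale by n/rank, cumulative min, cap."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


def oracle_mww_4v4(a, b):
    """Full 70-assignment enumeration with its own midrank computation."""
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(8)
    i = 0
    sorted_vals = pooled[order]
    while i < 8:
        j = i
        while j < 8 and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2
        i = j
    u_obs = ranks[:4].sum() - 10
    dev = abs(u_obs - 8)
    hits = 0
    for combo in itertools.combinations(range(8), 4):
        u = ranks[list(combo)].sum() - 10
        if abs(u - 8) >= dev - 1e-9:
            hits += 1
    return hits / 70


# ---------------------------------------------------------------------------
# Size factors


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        arr = np.tile([[10], [20], [30]], (1, 4))
        assert size_factors(arr) == pytest.approx([1, 1, 1, 1])

    def test_doubled_sample_splits_geometrically(self):
        """B = 2A exactly: factors (1/sqrt2, sqrt2), ratio 2."""
        a = np.array([10, 30, 50])
        arr = np.column_stack([a, 2 * a])
        f = size_factors(arr)
        assert f == pytest.approx([1 / math.sqrt(2), math.sqrt(2)])

    def test_planted_factor_recovery(self):
        cfg = SimulationConfig(n_loci=1500, frac_senescence_de=0.0, seed=21)
        cm, truth = simulate_counts(cfg)
        est = size_factors(cm)
        planted = truth.size_factors
        # identifiable only up to a common scale
        ratio = est / planted
        rel_err = np.abs(ratio / np.exp(np.mean(np.log(ratio))) - 1)
        assert (rel_err < 0.10).all()

    def test_all_zero_row_requires_fallback(self):
        arr = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="fallback"):
            size_factors(arr)
        f = size_factors(arr, allow_positive_fallback=True)
        assert np.all(f > 0)

    def test_matches_pydeseq2(self, rng):
        """Independent cross-check against the DESeq2 reference estimator."""
        from pydeseq2.preprocessing import deseq2_norm

        counts = rng.negative_binomial(10, 0.05, size=(400, 8))
        _, sf = deseq2_norm(pd.DataFrame(counts.T))  # samples x genes there
        assert size_factors(counts) == pytest.approx(np.asarray(sf).ravel(), rel=1e-9)


# ---------------------------------------------------------------------------
# NB exact test


class TestNbExactTest:
    def test_symmetric_split_at_mode_is_one(self):
        p = nb_exact_test([5, 5], [5, 5], [1, 1], [1, 1])
        assert p == pytest.approx(1.0)

    def test_poisson_limit_conditional_binomial(self):
        """1v1, total 4, observed (0,4): Binomial(4, 1/2) tail = 2/16."""
        assert conditional_exact_p(0, 4, 1, 1, 2.0, 0.0) == pytest.approx(0.125)

    def test_all_zero_locus_is_one(self):
        assert nb_exact_test([0, 0], [0, 0], [1, 1], [1, 1]) == 1.0

    def test_shrunk_mode_requires_trend(self):
        with pytest.raises(ValueError, match="trend"):
            nb_exact_test([1, 2], [3, 4], [1, 1], [1, 1], dispersion_mode="shrunk")
        p = nb_exact_test(
            [1, 2], [3, 4], [1, 1], [1, 1],
            dispersion_mode="shrunk", trend=DispersionTrend(0.05, 1.0),
        )
        assert 0 < p <= 1

    @pytest.mark.parametrize("alpha", [0.0, 0.05, 0.4])
    @pytest.mark.parametrize("n_a,n_b", [(4, 4), (2, 3)])
    def test_matches_enumeration_for_all_small_totals(self, alpha, n_a, n_b):
        """Exhaustive agreement with the enumeration oracle, totals <= 30."""
        for total in range(0, 31, 3):
            mu0 = total / (n_a + n_b) if total else 1.0
            for k_a in range(total + 1):
                got = conditional_exact_p(k_a, total, n_a, n_b, max(mu0, 1e-9), alpha)
                want = oracle_conditional_p(k_a, total, n_a, n_b, max(mu0, 1e-9), alpha)
                assert got == pytest.approx(want, abs=1e-12)

    def test_size_factor_equalization(self):
        """Scaling one group's counts and factors together changes nothing."""
        p1 = nb_exact_test([10, 12, 9, 11], [25, 30, 28, 27], [1] * 4, [1] * 4)
        p2 = nb_exact_test([10, 12, 9, 11], [50, 60, 56, 54], [1] * 4, [2] * 4)
        assert p1 == pytest.approx(p2)


# ---------------------------------------------------------------------------
# MWW


class TestMww:
    def test_complete_separation_4v4(self):
        assert mww_test([1, 2, 3, 4], [5, 6, 7, 8]) == pytest.approx(2 / 70)

    def test_constant_data_is_one(self):
        assert mww_test([3, 3, 3], [3, 3, 3]) == 1.0

    def test_exact_path_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            a = rng.integers(0, 6, 4).astype(float)  # ties likely
            b = rng.integers(0, 6, 4).astype(float)
            assert mww_test(a, b) == pytest.approx(oracle_mww_4v4(a, b), abs=1e-12)

    def test_normal_path_matches_scipy_asymptotic(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(50):
            a = rng.normal(size=6)
            b = rng.normal(size=7)
            want = mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
            assert mww_test(a, b) == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------------------
# t-test


class TestTTest:
    def test_identical_groups_is_one(self):
        assert t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_degenerate_constant_groups(self):
        assert t_test([10, 10], [10, 10]) == 1.0
        assert t_test([10, 10], [12, 12]) == 0.0

    def test_null_type_one_error_calibrated(self, rng):
        """Welch at alpha=0.01 rejects a true null about 1% of the time."""
        rejections = 0
        reps = 10_000
        a = rng.normal(size=(reps, 4))
        b = rng.normal(size=(reps, 4))
        for i in range(reps):
            if t_test(a[i], b[i]) <= 0.01:
                rejections += 1
        assert 0.005 <= rejections / reps <= 0.02


# ---------------------------------------------------------------------------
# BH


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_stepup_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 50)))
            assert bh_adjust(p) == pytest.approx(oracle_bh(p), abs=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# run_comparison / run_all_comparisons


def _nb_draws(rng, mean, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=size)


class TestRunComparison:
    def _matrix(self, rng, n_loci, mean_b_factor=1.0, mean=200.0, alpha=0.05,
                frac_planted=0.3):
        """Plant the fold change in a 30% subset so that median-of-ratios
        normalization (which assumes most loci unchanged) stays valid."""
        counts = _nb_draws(rng, mean, alpha, (n_loci, 36))
        n_planted = int(round(frac_planted * n_loci)) if mean_b_factor != 1.0 else 0
        # columns 0-3: WT/HD (group A); columns 4-7: WT/12DAA (group B)
        if n_planted:
            counts[:n_planted, 4:8] = _nb_draws(
                rng, mean * mean_b_factor, alpha, (n_planted, 4)
            )
        cm = make_count_matrix(counts)
        planted_ids = cm.locus_ids[:n_planted]
        return cm, planted_ids

    def _spec(self):
        return ComparisonSpec("HDvs12", (0, 1, 2, 3), (4, 5, 6, 7))

    def test_conjunction_requires_all_four(self, rng):
        cm, planted = self._matrix(rng, 60, mean_b_factor=16.0)
        res = run_comparison(cm, self._spec(), Thresholds())
        t = res.table
        # is_de never true when any single test misses its threshold
        violating = t.is_de & ~(
            (t.q_nbA <= 0.01) & (t.q_nbB <= 0.01) & (t.p_mww <= 0.05) & (t.p_t <= 0.01)
        )
        assert not violating.any()
        assert t.loc[planted, "is_de"].any()  # 16-fold changes are detectable

    def test_direction_follows_fold_change(self, rng):
        cm, planted = self._matrix(rng, 40, mean_b_factor=8.0)
        res = run_comparison(cm, self._spec(), Thresholds())
        de_planted = res.table.loc[planted]
        assert (de_planted.loc[de_planted.is_de, "direction"] == "up").all()

    def test_planted_sixteenfold_power(self, rng):
        """A planted log2fc of 4 at mu=200, alpha=0.05 is nearly always called."""
        cm, planted = self._matrix(rng, 100, mean_b_factor=16.0)
        res = run_comparison(cm, self._spec(), Thresholds())
        assert res.table.loc[planted, "is_de"].mean() >= 0.90

    def test_null_call_rate_conservative(self, rng):
        cm, _ = self._matrix(rng, 400, mean_b_factor=1.0)
        res = run_comparison(cm, self._spec(), Thresholds())
        assert res.table.is_de.mean() <= 0.01

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            ComparisonSpec("bad", (0,), (1, 2))


@pytest.fixture(scope="module")
def small_run():
    cfg = SimulationConfig(n_loci=120, seed=17)
    cm, truth = simulate_counts(cfg)
    return cm, truth, run_all_comparisons(cm)


class TestRunAllComparisons:
    def test_twelve_results_three_unions(self, small_run):
        _, _, res = small_run
        assert len(res.results) == 12
        assert len(res.genotype_sets) == 3

    def test_genotype_set_is_union_of_timepoints(self, small_run):
        _, _, res = small_run
        for pair in ("WT_vs_gpcA1", "WT_vs_gpcA1_gpcB2", "gpcA1_vs_gpcA1_gpcB2"):
            union = set()
            per_tp = []
            for tp in ("HD", "12DAA", "22DAA"):
                ids = res.results[f"{tp}:{pair}"].de_ids
                union |= ids
                per_tp.append(ids)
            assert res.genotype_sets[pair] == union
            assert len(union) <= sum(len(s) for s in per_tp)
            if all(
                not (per_tp[i] & per_tp[j])
                for i in range(3)
                for j in range(i + 1, 3)
            ):
                assert len(union) == sum(len(s) for s in per_tp)

    def test_missing_design_cell_reported(self, small_run):
        cm, _, _ = small_run
        crippled = make_count_matrix(
            cm.counts.to_numpy()[:, :32], design=cm.samples[:32]
        )
        with pytest.raises(ValueError, match="design cell"):
            comparison_plan(crippled)
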