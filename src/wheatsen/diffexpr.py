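"""Four-test consensus differential expression calling.

A locus is declared differentially expressed for a pairwise comparison
only when four tests agree simultaneously:

1. a conditional negative-binomial exact test with pooled per-group
   dispersion, BH-adjusted q <= 0.01;
2. the same exact test with per-locus dispersion shrunk toward a fitted
   mean-dispersion trend, BH-adjusted q <= 0.01;
3. a Mann-Whitney-Wilcoxon test on normalized counts, raw p <= 0.05;
4. a Welch t-test on log2-transformed normalized counts (pseudocount
   0.5), raw p <= 0.01.  The log scale is where NB counts are closest to
   homoskedastic, which keeps the Welch degrees of freedom near the
   nominal 2(n-1); on the linear scale the high-expression group
   dominates the variance and the test loses most of its power at small
   n.

The conjunction is deliberately conservative: its null rate is bounded by
the smallest of the four individual rates.  Library sizes are corrected
by median-of-ratios size factors before any test sees the data.

The exact test conditions on the total count of the two groups after
size-factor equalization: each group sum is modelled as a negative
binomial (a sum of i.i.d. NB replicates shares the success probability,
so the group sum is NB with size n/alpha), and the p-value is the summed
probability of all splits of the total no more likely than the observed
one.  With dispersion alpha -> 0 and equal effective sizes this reduces
to the conditional binomial test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .model import CountMatrix, Genotype, Thresholds, Timepoint, TIMEPOINT_ORDER

logger = logging.getLogger(__name__)

_LOG_TIE_TOL = 1e-7  # relative tolerance for probability ties in exact tests
_MIN_ALPHA = 1e-12  # below this the NB degenerates to Poisson

DispersionMode = Literal["pooled", "shrunk"]


# ---------------------------------------------------------------------------
# Normalization


def size_factors(cm_or_counts, allow_positive_fallback: bool = False) -> np.ndarray:
    """Median-of-ratios size factors, one per sample.

    For sample j: ``s_j = median_i(c_ij / g_i)`` where ``g_i`` is the
    geometric mean of locus i across samples and the median runs over loci
    with all-positive counts.  Normalized counts are ``c_ij / s_j``.

    If no locus is positive in every sample the strict estimator is
    undefined; with ``allow_positive_fallback=True`` the geometric mean is
    computed over positive entries only and the median over loci positive
    in the given sample.
    """
    if isinstance(cm_or_counts, CountMatrix):
        arr = cm_or_counts.counts.to_numpy(dtype=float)
    else:
        arr = np.asarray(cm_or_counts, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a loci x samples matrix")
    all_positive = (arr > 0).all(axis=1)
    if all_positive.any():
        sub = arr[all_positive]
        log_gm = np.log(sub).mean(axis=1)
        factors = np.exp(np.median(np.log(sub) - log_gm[:, None], axis=0))
    elif allow_positive_fallback:
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(arr)
        logs[~np.isfinite(logs)] = np.nan
        log_gm = np.nanmean(logs, axis=1)
        ratios = logs - log_gm[:, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    else:
        raise ValueError(
            "no locus has positive counts in every sample; "
            "rerun with allow_positive_fallback=True to use the "
            "positive-entry pseudo-reference"
        )
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValueError("degenerate size factors; check for empty samples")
    return factors


def normalize_counts(cm: CountMatrix, factors: np.ndarray | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(cm)
    return cm.counts / factors


# ---------------------------------------------------------------------------
# Dispersion estimation


def _moments_dispersion(norm_counts: np.ndarray) -> float:
    """Method-of-moments NB dispersion of one group (var = mu + a*mu^2)."""
    m = norm_counts.mean()
    if m <= 0 or len(norm_counts) < 2:
        return 0.0
    v = norm_counts.var(ddof=1)
    return max(0.0, (v - m) / (m * m))


def pooled_dispersion(norm_a: np.ndarray, norm_b: np.ndarray) -> float:
    """Average of the two within-group method-of-moments dispersions."""
    return 0.5 * (_moments_dispersion(norm_a) + _moments_dispersion(norm_b))


@dataclass(frozen=True)
class DispersionTrend:
    """Parametric mean-dispersion trend alpha(mu) = a0 + a1 / mu.

    The classic parametric trend for bulk RNA-seq: an asymptotic
    biological dispersion a0 plus a shot-noise-like 1/mu term.
    """

    a0: float
    a1: float

    def __call__(self, mu: float) -> float:
        if mu <= 0:
            return self.a0
        return max(self.a0 + self.a1 / mu, 0.0)


def fit_dispersion_trend(means: np.ndarray, dispersions: np.ndarray) -> DispersionTrend:
    """Least-squares fit of alpha ~ a0 + a1/mu over per-locus estimates.

    Loci with non-positive mean are dropped; zero dispersion estimates are
    kept (they inform the trend floor).  Coefficients are clipped at zero.
    """
    ok = means > 0
    mu = means[ok]
    al = dispersions[ok]
    if len(mu) < 2:
        return DispersionTrend(float(al.mean()) if len(al) else 0.0, 0.0)
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    coef, *_ = np.linalg.lstsq(X, al, rcond=None)
    return DispersionTrend(max(float(coef[0]), 0.0), max(float(coef[1]), 0.0))


# ---------------------------------------------------------------------------
# The conditional NB exact test


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x).astype(np.int64)


def _group_sum_logpmf(k: np.ndarray, n: int, mu: float, alpha: float) -> np.ndarray:
    """log pmf of the sum of n i.i.d. NB(mean mu, dispersion alpha) at k."""
    m = n * mu
    if alpha < _MIN_ALPHA:
        return stats.poisson.logpmf(k, m)
    r = n / alpha
    p = r / (r + m)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    s_a: Sequence[float],
    s_b: Sequence[float],
    dispersion_mode: DispersionMode = "pooled",
    trend: DispersionTrend | None = None,
    shrinkage_weight: float = 0.5,
) -> float:
    """Conditional negative-binomial exact test for one locus.

    Counts are equalized to a common library scale (divided by their size
    factors, rounded half-to-even), dispersion is estimated by within-group
    method of moments and either pooled across the two groups or shrunk
    toward ``trend`` with weight ``shrinkage_weight``, and the p-value is
    the total conditional probability of splits of the observed grand
    total that are no more likely than the observed split.

    Returns p in (0, 1]; an all-zero locus gives p = 1.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    s_a = np.asarray(s_a, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    if len(counts_a) < 2 or len(counts_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    norm_a = counts_a / s_a
    norm_b = counts_b / s_b
    eq_a = _round_half_even(norm_a)
    eq_b = _round_half_even(norm_b)
    k_a = int(eq_a.sum())
    k_b = int(eq_b.sum())
    total = k_a + k_b
    if total == 0:
        logger.debug("all-zero locus: p = 1")
        return 1.0
    n_a, n_b = len(eq_a), len(eq_b)
    mu0 = total / (n_a + n_b)
    alpha_mom = pooled_dispersion(norm_a, norm_b)
    if dispersion_mode == "pooled":
        alpha = alpha_mom
    elif dispersion_mode == "shrunk":
        if trend is None:
            raise ValueError("dispersion_mode='shrunk' requires a fitted trend")
        alpha = (1.0 - shrinkage_weight) * alpha_mom + shrinkage_weight * trend(mu0)
    else:
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
    return conditional_exact_p(k_a, total, n_a, n_b, mu0, alpha)


def conditional_exact_p(
    k_a: int, total: int, n_a: int, n_b: int, mu0: float, alpha: float
) -> float:
    k = np.arange(total + 1)
    logp = _group_sum_logpmf(k, n_a, mu0, alpha) + _group_sum_logpmf(
        total - k, n_b, mu0, alpha
    )
    logp = logp - logsumexp(logp)
    obs = logp[k_a]
    p = float(np.exp(logsumexp(logp[logp <= obs + _LOG_TIE_TOL])))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon


def mww_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p with midrank tie handling.

    For combined n <= 10 the null is enumerated exactly over all group
    assignments: p = P(|U - E[U]| >= observed).  Larger samples use the
    normal approximation with tie-corrected variance (no continuity
    correction).  All values identical gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    eu = n_a * n_b / 2
    dev_obs = abs(u_obs - eu)
    if n <= 10:
        offset = n_a * (n_a + 1) / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n_a):
            u = ranks[list(combo)].sum() - offset
            if abs(u - eu) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return count / total
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var_u = n_a * n_b / 12 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 1.0
    z = dev_obs / math.sqrt(var_u)
    return min(1.0, 2 * stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Welch t-test


def t_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom.

    Degenerate inputs: both groups constant with equal means -> p = 1;
    both constant with different means -> p = 0 (the zero-variance limit).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 1.0
        logger.debug("zero-variance groups with unequal means: p = 0 limit")
        return 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Running comparisons


@dataclass(frozen=True)
class ComparisonSpec:
    """Two disjoint sample groups to compare, identified by column index."""

    label: str
    cols_a: tuple[int, ...]
    cols_b: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.cols_a) & set(self.cols_b):
            raise ValueError(f"{self.label}: groups overlap")
        if len(self.cols_a) < 2 or len(self.cols_b) < 2:
            raise ValueError(f"{self.label}: each group needs >= 2 samples")


@dataclass
class ComparisonResult:
    """Per-locus statistics for one pairwise comparison.

    ``log2fc`` is group B over group A on normalized means with a 0.5
    pseudocount on both means; ``direction`` is "up" when B exceeds A.
    """

    label: str
    table: pd.DataFrame  # columns: p_nbA, q_nbA, p_nbB, q_nbB, p_mww, p_t, log2fc, direction, is_de

    @property
    def de_ids(self) -> set[str]:
        return set(self.table.index[self.table["is_de"]])

    def de_ids_by_direction(self, direction: str) -> set[str]:
        m = self.table["is_de"] & (self.table["direction"] == direction)
        return set(self.table.index[m])


def run_comparison(
    cm: CountMatrix,
    spec: ComparisonSpec,
    th: Thresholds = Thresholds(),
    factors: np.ndarray | None = None,
) -> ComparisonResult:
    """Apply the four tests to every locus and take their conjunction.

    Size factors are estimated on the full matrix unless supplied.  The
    shrinkage trend for the second NB test is fitted across all loci from
    the per-locus pooled method-of-moments estimates of this comparison.
    """
    if factors is None:
        factors = size_factors(cm, allow_positive_fallback=True)
    arr = cm.counts.to_numpy(dtype=float)
    ca = arr[:, list(spec.cols_a)]
    cb = arr[:, list(spec.cols_b)]
    sa = factors[list(spec.cols_a)]
    sb = factors[list(spec.cols_b)]
    norm_a = ca / sa
    norm_b = cb / sb

    # per-locus moments for the shrinkage trend
    mu_all = np.concatenate([norm_a, norm_b], axis=1).mean(axis=1)
    alpha_mom = np.array(
        [pooled_dispersion(norm_a[i], norm_b[i]) for i in range(cm.n_loci)]
    )
    trend = fit_dispersion_trend(mu_all, alpha_mom)

    eq_a = _round_half_even(norm_a)
    eq_b = _round_half_even(norm_b)
    n_a, n_b = eq_a.shape[1], eq_b.shape[1]

    p_nbA = np.empty(cm.n_loci)
    p_nbB = np.empty(cm.n_loci)
    p_mww = np.empty(cm.n_loci)
    p_t = np.empty(cm.n_loci)
    for i in range(cm.n_loci):
        k_a = int(eq_a[i].sum())
        total = k_a + int(eq_b[i].sum())
        if total == 0:
            p_nbA[i] = p_nbB[i] = 1.0
        else:
            mu0 = total / (n_a + n_b)
            a_pool = alpha_mom[i]
            a_shrunk = 0.5 * a_pool + 0.5 * trend(mu0)
            p_nbA[i] = conditional_exact_p(k_a, total, n_a, n_b, mu0, a_pool)
            p_nbB[i] = conditional_exact_p(k_a, total, n_a, n_b, mu0, a_shrunk)
        p_mww[i] = mww_test(norm_a[i], norm_b[i])
        # t on the log scale: NB counts are near-homoskedastic there, so
        # Welch keeps close to the nominal 2(n-1) degrees of freedom
        p_t[i] = t_test(np.log2(norm_a[i] + 0.5), np.log2(norm_b[i] + 0.5))

    q_nbA = bh_adjust(p_nbA)
    q_nbB = bh_adjust(p_nbB)

    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    log2fc = np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5)
    direction = np.where(log2fc < 0, "down", "up")
    is_de = (
        (q_nbA <= th.fdr_alpha)
        & (q_nbB <= th.fdr_alpha)
        & (p_mww <= th.mww_alpha)
        & (p_t <= th.t_alpha)
    )
    n_zero_dir = int((is_de & (log2fc == 0)).sum())
    if n_zero_dir:
        logger.warning("%d DE loci with log2fc exactly 0 reported as 'up'", n_zero_dir)

    table = pd.DataFrame(
        {
            "p_nbA": p_nbA,
            "q_nbA": q_nbA,
            "p_nbB": p_nbB,
            "q_nbB": q_nbB,
            "p_mww": p_mww,
            "p_t": p_t,
            "log2fc": log2fc,
            "direction": direction,
            "is_de": is_de,
        },
        index=cm.counts.index,
    )
    logger.info("%s: %d / %d loci DE", spec.label, int(is_de.sum()), cm.n_loci)
    return ComparisonResult(spec.label, table)


# ---------------------------------------------------------------------------
# The full comparison plan


WT_TIME_LABELS = ("WT:HD_vs_12DAA", "WT:HD_vs_22DAA", "WT:12DAA_vs_22DAA")
GENOTYPE_PAIRS: tuple[tuple[str, Genotype, Genotype], ...] = (
    ("WT_vs_gpcA1", Genotype.WT, Genotype.gpcA1),
    ("WT_vs_gpcA1_gpcB2", Genotype.WT, Genotype.gpcA1_gpcB2),
    ("gpcA1_vs_gpcA1_gpcB2", Genotype.gpcA1, Genotype.gpcA1_gpcB2),
)


def comparison_plan(cm: CountMatrix) -> list[ComparisonSpec]:
    """The twelve pairwise comparisons of the analysis.

    Three time-course comparisons within WT, plus the three genotype
    pairs within each of the three time points.  Genotype-level DE sets
    are later formed as unions of the per-time-point results.
    """
    specs: list[ComparisonSpec] = []
    time_pairs = [
        (WT_TIME_LABELS[0], Timepoint.HD, Timepoint.D12),
        (WT_TIME_LABELS[1], Timepoint.HD, Timepoint.D22),
        (WT_TIME_LABELS[2], Timepoint.D12, Timepoint.D22),
    ]
    for label, t_a, t_b in time_pairs:
        cols_a = cm.columns_for(Genotype.WT, t_a)
        cols_b = cm.columns_for(Genotype.WT, t_b)
        if not cols_a or not cols_b:
            raise ValueError(f"missing design cell for {label}")
        specs.append(ComparisonSpec(label, tuple(cols_a), tuple(cols_b)))
    for tp in TIMEPOINT_ORDER:
        for pair_label, g_a, g_b in GENOTYPE_PAIRS:
            cols_a = cm.columns_for(g_a, tp)
            cols_b = cm.columns_for(g_b, tp)
            if not cols_a or not cols_b:
                raise ValueError(f"missing design cell {g_a.value}/{tp.value} or {g_b.value}/{tp.value}")
            specs.append(
                ComparisonSpec(f"{tp.value}:{pair_label}", tuple(cols_a), tuple(cols_b))
            )
    return specs


@dataclass
class AllComparisons:
    """Results of the full plan plus genotype-level union DE sets."""

    results: dict[str, ComparisonResult]
    genotype_sets: dict[str, set[str]]  # label -> union of per-timepoint DE ids

    def wt_time_results(self) -> tuple[ComparisonResult, ComparisonResult, ComparisonResult]:
        return (
            self.results[WT_TIME_LABELS[0]],
            self.results[WT_TIME_LABELS[1]],
            self.results[WT_TIME_LABELS[2]],
        )

    @property
    def senescence_de_ids(self) -> set[str]:
        out: set[str] = set()
        for label in WT_TIME_LABELS:
            out |= self.results[label].de_ids
        return out


def run_all_comparisons(
    cm: CountMatrix, th: Thresholds = Thresholds()
) -> AllComparisons:
    """Run the twelve comparisons and form the three genotype-level sets."""
    factors = size_factors(cm, allow_positive_fallback=True)
    results: dict[str, ComparisonResult] = {}
    for spec in comparison_plan(cm):
        results[spec.label] = run_comparison(cm, spec, th, factors=factors)
    genotype_sets: dict[str, set[str]] = {}
    for pair_label, _g_a, _g_b in GENOTYPE_PAIRS:
        union: set[str] = set()
        for tp in TIMEPOINT_ORDER:
            union |= results[f"{tp.value}:{pair_label}"].de_ids
        genotype_sets[pair_label] = union
    return AllComparisons(results, genotype_sets)
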