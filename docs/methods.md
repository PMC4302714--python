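# Methods

## The statistical model

Counts for locus *i* in sample *j* are modelled negative-binomial with
mean `s_j · μ_ij` and variance `μ + α_i μ²`, where `s_j` is a per-sample
library-size factor and `α_i` a locus dispersion.  Size factors are the
median-of-ratios estimator: for sample *j*,
`s_j = median_i (c_ij / g_i)` with `g_i` the geometric mean of locus *i*
across samples, the median taken over loci with all-positive counts.
When no locus is positive everywhere the strict estimator is undefined;
an explicit opt-in fallback restricts the geometric mean to positive
entries.  Factors are identifiable only up to a common scale; tests are
scale-invariant so no rescaling is applied.

### The four-test consensus

A locus is differentially expressed for a pairwise comparison only when
four tests agree simultaneously:

1. **Conditional NB exact test, pooled dispersion** (BH q ≤ 0.01).
   Counts are equalized to a common library scale (divided by size
   factors, rounded half-to-even — a documented distortion, negligible
   at the depths tested).  The two group sums are NB: a sum of *n*
   i.i.d. NB(μ, α) draws shares the success probability, giving
   NB(size n/α).  Conditioning on the grand total *S*, the p-value is
   the summed probability of all splits of *S* no more likely than the
   observed one.  With α → 0 and equal effective sizes this reduces to
   the conditional binomial test (verified by enumeration in the test
   suite).  Dispersion is method-of-moments within each group,
   `α = max(0, (s² − m)/m²)`, averaged across the two groups.
2. **The same exact test, trend-shrunk dispersion** (BH q ≤ 0.01).  A
   parametric mean-dispersion trend `α(μ) = a₀ + a₁/μ` is least-squares
   fitted across all loci of the comparison and the per-locus estimate
   is shrunk halfway toward it.  The two variants stand in for the two
   count-model procedures commonly used for this design while keeping a
   single, enumerable statistic.
3. **Mann–Whitney–Wilcoxon** on normalized counts (p ≤ 0.05).  For
   combined n ≤ 10 the null is enumerated exactly over all group
   assignments with midrank ties, `p = P(|U − E[U]| ≥ observed)`;
   larger samples use the normal approximation with tie-corrected
   variance and no continuity correction.  Note that at 4 vs 4 the
   smallest attainable two-sided p is 2/70 ≈ 0.029, so this test passes
   only on complete separation of the two groups.
4. **Welch t-test on log2(normalized + 0.5)** (p ≤ 0.01).  The log
   scale is where NB counts are nearest homoskedastic: on the linear
   scale the variance of the high-expression group dominates and the
   Satterthwaite degrees of freedom collapse toward n − 1 of one group
   (critical t ≈ 5.5 at p = 0.01 for n = 4), discarding most of the
   test's power at the fold changes of interest.  On the log scale the
   group variances are comparable (≈ α + 1/μ), df stays near 2(n − 1),
   and measured per-transition power at four-fold changes rises from
   0.73–0.90 to ≥ 0.95 without affecting type-I control (the null
   calibration test bounds the consensus false-call rate at 1%).  The
   `t_test` primitive itself is scale-agnostic; the log transform is
   applied by the comparison runner.

BH adjustment (statsmodels step-up) is applied per comparison to the
two NB tests only; MWW and *t* use raw thresholds.  The conjunction is
deliberately conservative — its null rate is bounded by the smallest
individual rate — trading power for a low false-positive rate, which is
why the planted-truth tests measure both sensitivity and observed FDR.

Fold changes are `log2((mean_B + 0.5) / (mean_A + 0.5))` on normalized
group means; direction ties at exactly 0 cannot survive the thresholds
but would be reported "up" with a warning.

### The comparison plan

Twelve comparisons: HD vs 12 DAA, HD vs 22 DAA and 12 vs 22 DAA within
WT, plus the three genotype pairs within each time point.  Genotype-
level DE sets are unions of the per-time-point sets — a locus counts as
GPC-responsive if it responds at any stage.  The senescence-DE set is
the union of the three WT time comparisons.

### Profiles and set algebra

Transition 1 (HD→12) and transition 2 (12→22) are each Up, Down, or
Flat from the comparison's consensus call and direction; the eight
non-Flat-Flat combinations are the profile classes.  A locus flat in
both transitions but DE endpoint-to-endpoint folds into Up-Up or
Down-Down; the fold-in never overrides a class defined by significant
transitions, and loci flat everywhere stay unassigned, so the classes
partition the senescence-DE set exactly.

High-confidence sets intersect a single-mutant comparison with the
double-mutant comparison; the redundancy evidence is the double-only
Venn cell plus the triple intersection, and the redundancy percentage
is (double_only + triple) / (double_only + triple + gpc1_only +
gpc2_only).  Reported percentages round half-away-from-zero to one
decimal.

### Enrichment

Per term, a one-sided hypergeometric upper tail on the 2×2 table of
query membership vs term annotation within the annotated universe;
`expected = annotated × |query| / |universe|`.  No ontology-graph
weighting and no multiple-testing correction — each term is an
independent "classic" test, and ancestor propagation is the input's
responsibility.

## Annotation building

`cluster_merge_intervals` merges intervals whose separation
`start_next − end_prev` is ≤ the gap parameter on half-open
coordinates, so bookended intervals merge even at gap 0, matching
overlapping-or-bookended cluster semantics; merging never crosses
contigs (the A/B sub-genomes are distinct contig namespaces).  Novel
regions are maximal runs of depth ≥ 10 after masking known loci,
clustered at ≤ 1 kb.  When several coverage tracks are supplied they
are combined by per-position maximum before thresholding — the least
lossy rule for a detection threshold; the combination rule was not
otherwise constrained.

## The synthetic experiment

The generator draws the full 3 × 3 × 4 design.  Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| loci | 2,000 | enough for stable recovery statistics per class |
| baseline mean | log-uniform [100, 2000] | moderately-to-highly expressed loci, the regime that survives the low-count filter |
| dispersion α | log-uniform [0.01, 0.1] | typical well-replicated bulk RNA-seq |
| size factors | uniform [0.5, 2] | two-fold library-size spread |
| senescence-DE fraction | 0.30 | 600 DE loci ⇒ ~75 per profile class |
| planted \|log2FC\| | 2.0 per transition | configurable |
| profile-class weights | uniform 1/8 | |
| regulator fractions (of DE) | 0.15 / 0.10 / 0.20 GPC1/GPC2/redundant | mirrors the relative sizes of single-gene vs redundant categories in this system |

Regulator semantics: GPC1 loci lose the temporal response in **both**
mutants (GPC1 loss is epistatic); GPC2 loci respond normally in the
single *gpc-A1* mutant and are flat only in the double; redundant loci
are flat in the double and keep a **half-strength** log-fold response in
the single mutant (GPC2 partially compensates).  Truth-label
consistency is verified analytically on the mean model before sampling.

Annotation inputs: truth loci are placed with inter-locus gaps above the
1 kb clustering distance so distinct loci can never merge; transcript-
supported loci are tiled by 2–5 overlapping fragments whose union is
exactly the locus; coverage-only loci carry Poisson depth floored at the
detection threshold (the generator guarantees discoverability end to
end); background depth is ≤ 3.

What the generator does **not** emulate: read-level errors and mapping
ambiguity (uniqueness is an input flag), homoeolog cross-mapping, GC or
length biases, correlated dispersion across loci, or batch structure.
Recovery results on synthetic data therefore demonstrate correctness of
the inference chain under the stated model, not robustness to the
artefacts of real wheat libraries.

## Known limitations

* **Redundant-regulation identifiability.**  With a half-strength
  response in the single mutant, both comparisons flanking a redundant
  locus (WT vs single, single vs double) sit at two-fold, where the
  conservative conjunction detects with probability q ≈ 0.85 (union
  over time points).  A redundant locus lands in a redundancy cell only
  when both flanking comparisons detect (triple) or neither does
  (double-only), probability q² + (1 − q)² ≈ 0.74; detection of exactly
  one side misfiles it into a high-confidence single-gene cell.  This
  is a property of the three-genotype design, not of the
  implementation, and asymmetric attenuation choices score strictly
  worse.  Overall regulator-label recovery (all three classes pooled)
  is ≈ 0.86.
* The exact test's O(S) enumeration makes deeply covered loci the
  runtime bottleneck (~2 minutes for 2,000 loci × 12 comparisons on one
  CPU); problem sizes in the drivers and tests were chosen at that
  scale.
* The MWW exact path enumerates only up to combined n = 10; beyond
  that the tie-corrected normal approximation is used.
* Count equalization rounds normalized counts to integers; at depths
  below ~10 this rounding can shift exact-test p-values noticeably.
* The low-count filter's design cells are inferred from the sample
  sheet; unbalanced designs are allowed (with a warning below two
  replicates) but the exact tests require ≥ 2 samples per group.
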