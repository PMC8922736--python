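# Methods

`degbench` packages the statistical machinery needed to benchmark
differential-expression (DE) methods on two-condition RNA-seq count data with
large per-condition sample sizes: a rank-based DEG pipeline, a deliberately
plain parametric comparator, two benchmark constructions (permutation-null
and semi-synthetic), FDR/power evaluation, a negative-binomial goodness-of-fit
diagnostic, and a count simulator that controls every ingredient of the data-
generating process.

## The data model

A dataset is a gene-by-sample matrix `M` of non-negative integer read counts
together with a two-level condition label vector `C`. `X` and `Y` denote the
per-condition column blocks of `M`. Condition levels are ordered
lexicographically unless an explicit order is supplied; all fold changes are
reported as level 2 versus level 1 under that ordering. Samples are aligned by
identifier, never by position, so permuted label tables remain unambiguous.

## The Wilcoxon rank-sum DEG pipeline

1. **Low-expression filter.** Keep gene `g` iff its CPM (against raw library
   sizes) reaches `T = 10 / (median library size in millions)` in at least `k`
   samples, with `k` the smaller group size, and its total count is >= 15.
   This is a fixed, fully specified rule of the `filterByExpr` family; the
   data-driven `T` keeps the rule meaningful across sequencing depths.
2. **TMM scaling factors.** Reference sample: the one whose 75th-percentile
   count/library-size ratio is closest to the mean of that quantity (ties to
   the lowest index). For each other sample, per-gene log2 ratios `M_g` and
   mean log2 abundances `A_g` are formed over genes positive in both samples;
   genes are doubly trimmed by rank (30% per tail on `M`, 5% per tail on `A`;
   boundary ties resolved by average ranks), and the factor is `2**f` with `f`
   the inverse-variance weighted mean of the surviving `M_g`
   (`v_g = (N_j - y_gj)/(N_j y_gj) + (N_r - y_gr)/(N_r y_gr)` from the delta
   method). Factors are rescaled to geometric mean 1; a sample whose trim
   leaves fewer than 10 genes gets factor 1 with a warning. The implementation
   agrees with the reference R implementation of TMM to machine precision on
   dense random matrices (cross-checked in the test suite).
3. **CPM.** `count / (library size x factor) x 1e6`. Effective (TMM-scaled)
   sizes are the default; raw sizes are a switch, since published pipelines
   differ on this detail.
4. **Rank-sum test.** Per kept gene, a two-sided Wilcoxon rank-sum
   (Mann-Whitney) test on the two CPM groups. The exact null distribution is
   enumerated when both group sizes are <= 25 and the pooled values are
   tie-free; otherwise the normal approximation with tie-corrected variance
   `n1 n2 /12 [(N+1) - sum(t^3 - t)/(N(N-1))]` and a continuity correction of
   1/2 is used. The two-sided p doubles the smaller tail, capped at 1. The
   test only uses ranks, so it is invariant to monotone transformations and
   insensitive to single outlier magnitudes.
5. **Benjamini-Hochberg.** Step-up q-values over the kept genes
   (`q_(i) = min_{j>=i} m p_(j) / j`, capped at 1); filtered genes carry
   missing p and q. Discovery at threshold `t` uses the strict inequality
   `q < t`.

An important small-sample fact falls out of the exact test: with `n` samples
per condition the smallest achievable p-value is `2 / C(2n, n)` (5.83e-4 at
n = 7), so below 8 samples per condition BH at 1% can never reject — the
pipeline is safe but nearly powerless there, which is why it is a
large-sample recommendation.

## The NB-Wald comparator

A minimal parametric foil, intentionally without the robustness machinery of
production tools (no dispersion shrinkage, no outlier refitting, no
moderation): per kept gene, the negative-binomial likelihood with
group-specific means, offsets equal to log effective library sizes, and one
gene-wise dispersion `phi` (variance `mu + phi mu^2`) is maximized. The
dispersion is profiled over a 25-point log-spaced grid on [1e-4, 10] refined
by vectorized golden-section search in `log(phi)` (15 iterations; final
bracket ~3e-4 in log units); group means for fixed `phi` are fitted by
damped Newton steps on the concave per-group log-likelihood. The Wald
statistic is `(log mu2 - log mu1) / SE` with the SE from observed information
at the optimum, and a two-sided normal p-value. It is not a replica of any
published tool; its role is to exhibit how a correctly specified parametric
test degrades when the NB assumption is violated.

## Benchmark constructions

**Permutation-null datasets.** The labels in `C` are uniformly permuted `B`
times while `M` is untouched; every discovery on a permuted dataset is a
false positive. Summaries: per-permutation discovery counts, the fraction of
permutations yielding more discoveries than the original labels, per-gene
identification frequencies, and the overlap of frequent false positives with
the original discovery set.

**Semi-synthetic datasets.** Given a truth set (from the simulator, or the
intersection of several methods' discoveries at a very small FDR threshold —
1e-6 by default — when no ground truth exists), `k = round(fraction x |truth|)`
true DEGs are sampled and keep their original rows in both conditions; every
other gene's pooled row is uniformly permuted across the two conditions and
split back by original column positions. Selected genes carry genuine signal;
all others are exchangeable across conditions by construction, so their
rank-sum p-values are stochastically no smaller than uniform. Down-sampling
to `n` columns per condition is uniform without replacement with the truth
set unchanged. Per-gene and per-replicate randomness derives from
`(seed, index)` sub-streams, so results do not depend on traversal order,
and replicates are reproducible from a single seed.

Filtering is re-run inside every permuted, semi-synthetic, or down-sampled
dataset (the kept-gene set is dataset-specific); callers who want a frozen
gene universe can pre-subset the parent matrix.

## Evaluation

FDP = |discoveries \ truth| / |discoveries| (0 when nothing is discovered);
the FDR of a method at a threshold is estimated as the mean FDP over
replicates, and power as the mean fraction of true DEGs discovered. Because
comparing power at equal *nominal* FDR is meaningless when actual FDRs
differ, power is also reported at matched actual FDR: each method's
(actual FDR, power) pairs over the threshold sweep are made non-decreasing by
the isotonic upper envelope (running maximum after sorting) and linearly
interpolated; queries outside the observed range are missing rather than
extrapolated.

## NB goodness of fit ("poorness")

For one gene under one condition, counts are divided by per-sample effective
size factors (effective library size over its mean), rounded, and tabulated
over cells `0..max` plus one open tail cell. The NB law has `size = 1/phi`
fixed (the dispersion under audit — by default the gene's own
profile-likelihood estimate, but any externally estimated value can be
supplied) and mean equal to the sample mean, the fixed-size ML estimate.
Pearson `X^2` is summed over cells with positive expectation, `df = cells - 2`,
and poorness is `-log10(p)` from the upper chi-square tail. Fewer than 8
observations, a constant vector, or `df <= 0` yield a degenerate (missing)
row. Group comparisons treat each (gene, condition) pair as one observation;
an aggregation to one value per gene (max over conditions) is provided and is
what the bundled analyses use.

Numerical care: the `X^2` sum collapses algebraically to
`sum(o_v^2 / e_v) - n` over observed values, so no 0..max table is ever
materialized; `-log10(p)` is evaluated through `log`-space survival functions,
with an asymptotic upper-incomplete-gamma expansion taking over when even the
log tail underflows, so extreme misfits stay finite and correctly ordered
rather than saturating.

Known behaviour of this construction: with sparse cells (large means or small
counts spread over many cells) the chi-square reference is anticonservative —
null p-values are not exactly uniform, and at very deep sequencing the
statistic is essentially a tail-distance measure. That is acceptable for its
role here, which is *comparative*: contaminated genes score orders of
magnitude worse than clean ones under identical processing. The calibration
tests therefore assert oracle-measured bounds (null p-values concentrated
away from 0, median poorness near -log10(0.5) in dense-cell regimes) rather
than exact uniformity.

## The simulator

Counts are drawn as `NB(mean = s_j mu_g f_g^[j in condition 2],
variance = mean + phi_g mean^2)` with:

| parameter | default | meaning |
|---|---|---|
| `G, n1, n2` | 5000, 100, 100 | genes; samples per condition |
| `pi` | 0.05 | DEG proportion; `round(pi G)` genes get a fold change |
| `log2fc` law | magnitude U(0.5, 3), random sign | effect sizes of true DEGs |
| `mu_g` law | log-normal(3, 1.5) (natural log) | baseline per-gene means |
| `phi_g` law | log-normal(-1.5, 0.8) | gene dispersions (median ~0.22) |
| `s_j` | (5e6/G) x log-normal(0, 0.3), normalized to mean 1 | per-sample depth factors |
| `epsilon` | 0 (0.02-0.05 in the benchmarks) | per-entry outlier probability |
| outlier law | multiplier log-uniform on [5, 50] | single-entry contamination |

Outliers replace an entry by `round(count x m)` and are recorded in a mask:
they emulate the sporadic, sample-specific extreme measurements that violate
the NB law in population-scale cohorts and that drive parametric false
positives. The generator does **not** emulate gene-gene correlation, batch
structure, per-tissue moment profiles, or compositional effects — passing
benchmarks here demonstrate behaviour under independent NB sampling with
contamination, not under every pathology of real cohorts. The depth scaling
keeps the median library size near `5e6 x mean(mu_g)` so the data-driven CPM
filter threshold lands in a realistic range at G = 5,000-20,000; per-gene
counts are correspondingly deep, which is the regime where the large-sample
phenomena of interest (parametric flooding, rank-test power) are cleanest.

## Problem sizes used in the bundled analyses

The analysis drivers and acceptance checks run at desk scale, chosen as the
smallest sizes at which the phenomena are unambiguous: parent datasets of
5,000 genes x (100+100) samples with 20 semi-synthetic replicates for the
FDR/power benchmarks (the full-scale design would use 50 replicates and 1,000
permutations); 2,000 genes x (50+50) samples, 50 label permutations, and 20
simulation seeds for the contamination diagnostics. 50 samples per condition
is used as the "large-sample" operating point throughout. The
rarely-flagged gene group in the goodness-of-fit contrast is capped at 200
genes (deterministic subsample) because its Pearson tabulation dominates
runtime otherwise.

## Known limitations

- The NB-Wald comparator's Wald p-values are mildly anticonservative at
  small n (a generic Wald property); its null calibration is checked at
  n = 100 per condition.
- The GoF chi-square approximation is anticonservative with sparse cells
  (see above); poorness values are comparative, not calibrated tail
  probabilities.
- `define_true_degs` inherits the biases of the methods being intersected;
  it exists because real data lack ground truth, and the simulator truth is
  preferred whenever the parent is synthetic.
- No covariate adjustment, no two-sample t-test route, and no re-implementation
  of published DE tools: external per-gene p-value tables can be evaluated
  through the adapter instead.
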