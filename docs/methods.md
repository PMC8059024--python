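# Methods

## Model and assumptions

The package tests the null hypothesis that a subjects × genes expression
submatrix `X` and an endpoint `Y` are independent, against the broad
alternative of *any* dependence between their pairwise-distance structures.
The statistic is the bias-corrected (U-centered) distance correlation `r_d`
and its t-statistic

    t_d = r_d / sqrt(1 − r_d²) · sqrt(ν),   ν = n(n−3)/2 − 1,

which is approximately t-distributed with ν degrees of freedom under
independence. The approximation is asymptotic in the number of variables:
it becomes exact as the dimensions of the two data matrices grow, for fixed
sample size `n`. No distributional model is fitted to the data; the only
substantive assumptions are exchangeable subjects, no missing values
(missingness is rejected, never imputed, because distance semantics under
missingness are undefined), and a meaningful Euclidean geometry on the
expression values (transform first if not).

Degenerate inputs — a gene set whose pairwise distances are all equal, a
single-category label vector, a survival vector with no events — are
flagged as errors rather than silently producing 0/0; the collection screen
converts them to per-row status flags so one degenerate set never aborts a
screen.

## Sidedness of the p-value

The t-test p-value is two-sided, `p = 2·P(T_ν > |t_d|)`. The endpoint side
of a gene-set test is always one-dimensional, and in that regime the null
distribution of `t_d` is noticeably right-skewed (empirical skewness ≈ 0.75
for 9-gene sets at n = 100, unit variance and mean ≈ 0). A one-sided
upper-tail p-value therefore over-rejects: its empirical level at nominal
5% is 6–7.5% in the simulation design below, whereas rejecting on |t_d|
holds the level at 4–5%. Two-sided rejection is also what keeps the
empirical level under the 6% bar that the simulation study checks. The
permutation module counts `|r_b| ≥ |r_observed|` so that it estimates the
same two-sided quantity it is meant to verify. A side effect worth knowing:
`r_d = 0` maps to p = 1, and p is a decreasing function of `t_d` only for
`t_d ≥ 0`.

## Permutation verification

The t approximation can misstate significance in the extreme tails (the
null p-values are slightly anti-conservative below p ≈ 0.04). The
permutation test applies a random subject permutation simultaneously to the
rows and columns of the U-centered endpoint matrix and recomputes only the
inner products — U-centering commutes with simultaneous row/column
permutation, so re-centering per replicate is unnecessary and each replicate
is O(n²) arithmetic. The add-one estimator `(1 + #extreme)/(B + 1)` never
returns zero; its floor at B = 10,000 is ≈ 1e-4. The collection screen
triggers the follow-up for sets with `p_t ≤ 0.05` by default (the
anti-conservative region starts near 0.04; the threshold is configurable and
the 0.04 caveat is the reason it should not be raised).

Agreement between the two p-values is good in the non-extreme range: for
56-gene sets at n = 50 and B = 10,000, |p_perm − p_t| stays below 0.02
whenever p_t ∈ [0.05, 0.5] (the acceptance suite checks exactly this). The
agreement degrades for smaller gene sets — at 8–10 genes discrepancies up
to ≈ 0.03 occur mid-range — which is another manifestation of the
approximation being asymptotic in dimension.

## Endpoint distances

* Quantitative: `|y_i − y_j|`.
* Categorical: 0/1 indicator of differing labels, compared by exact token
  equality. Merging of categories changes the metric and is deliberately
  left to the caller.
* Censored event time: with `u_1 < … < u_ś` the unique times at which
  events occurred, the distance between subjects i and j is the number of
  grid times `u_l` with `o_earlier ≤ u_l < o_later`, counted once for each
  of the two subjects that is an event. Inequalities are applied exactly as
  stated (strict `>` on the later observation, `≥` on the earlier): a
  subject observed exactly at an event time contributes through the `≥`
  side only, and duplicate event times enter the grid once. Two censored
  subjects are at distance zero. The metric depends on times only through
  their order (invariant to strictly monotone transforms), and when every
  subject is an event with distinct times it reduces to the rank distance
  |rank(o_i) − rank(o_j)|. Cost is O(n log n) here via cumulative counts on
  the sorted grid.

## Transforms

Two opt-in variance-equalising transforms are provided and never applied
silently, because equalising the contribution of lowly and highly expressed
genes is advisable in some applications and harmful in others: z-scoring
(per-gene mean 0, sample SD 1) and commensuration (per-gene centering, then
division by the gene's sum of pairwise absolute differences over unordered
subject pairs, computed in O(n log n) from order statistics). The
ordered/unordered pair convention in commensuration is a pure scale factor
and cancels in `r_d`.

## Screening and multiple testing

Every set in a collection receives a t-test p; permutation follow-ups run
for sets under the trigger threshold; rows are ranked by the permutation p
where present (t-test p breaks ties) and q-values are Benjamini–Hochberg on
that ranking p-value by default (Benjamini–Yekutieli, Holm and Bonferroni
are selectable). Gene matching is case-sensitive exact identifier matching,
with a warning when fewer than half of a set's genes are found. Per-set
permutation streams are derived from (seed, set index), so a screen is
reproducible regardless of evaluation order.

## Backward elimination of drivers

From the full matched set, each round evaluates every leave-one-out subset
and removes the gene whose exclusion minimises the p-value; the candidate
pool is the full set plus each surviving subset (sizes m … 1), and the
reported drivers are the minimum-p candidate. Squared Euclidean distances
are additive over genes, so the implementation keeps per-gene
squared-difference matrices and updates a running sum by subtraction —
O(n²) per candidate instead of O(n²·m). Numerical choices: candidates are
compared on −|t_d|, which at fixed n orders identically to p but stays
informative where the two-sided p underflows to 0 (without this, strongly
associated candidates tie at p = 0 and the parsimony tie-break collapses
the subset); ties in a round remove the gene with the lowest column index;
ties in the best p prefer the smaller subset; a degenerate candidate gets
p = 1 and elimination continues.

The selected subset's p-value is a selection criterion, not a type I error
rate — the hypothesis was chosen by looking at the data — and the results
object says so. For strict error control the whole elimination can be
re-run inside a permutation test; the selection-adjusted p compares the
observed best score with the best score each endpoint-permuted dataset
achieves given the same selection freedom.

When the planted drivers are redundant copies of one latent signal, the
minimum-p subset legitimately keeps only a few of them (extra copies add
noise faster than signal); full recovery of a planted driver group is
expected only when each driver contributes comparably and the per-gene
effect is moderate.

## Simulation harness

The generator reproduces the structure of a two-collection gene-set
simulation design. Collection A: 100 genes, 60 sets of 8–10 genes, 10
associated genes, exactly 10 sets containing at least one of them;
collection B: 1000 genes, 100 sets of 10–100, 10 associated genes, 20 sets
containing signal. Set sizes are uniform within the stated ranges; each
signal-bearing set contains 1–3 associated genes; membership is a function
of the master seed alone and fixed across replicates; per-replicate data
use independent substreams of the master seed, so every dataset is
bit-reproducible from (seed, replicate index).

A latent standard-normal subject vector L drives everything: null genes are
iid N(0,1); simple associated genes are `beta·L + noise_sd·N(0,1)` (defaults
beta = noise_sd = 1, i.e. 1:1 signal-to-noise — high power for simple
associations by n = 50–100); complex associated genes multiply the
coefficient by a per-subject random sign vector Z shared across the
associated genes. Endpoints: quantitative `y = L + N(0,1)`; categorical by
a median split of `L + N(0,1)` into two equal groups; survival with event
times Exponential(rate = e^L) censored by an independent Uniform(0, c),
where c is found by Brent root-finding on the Gauss–Hermite–integrated
censoring probability to hit the target censoring fraction (default 0.3).

What the generator does and does not emulate: it captures set-size
structure, overlap, signal dilution, latent-variable associations and
censoring, but not library-size effects, count noise, heavy tails, or
gene–gene correlation beyond the latent factor. Passing level/power checks
on it says the test is calibrated and sensitive under those idealised
conditions, not that effect sizes on real RNA-seq data will match.

A known detectability gap, documented rather than papered over: with Z
drawn independently of L, a complex gene relates to the endpoint only
through magnitudes (|gene| tracks |L|), and the collection-level power of
the test at these defaults is only ≈ 5–7% at n = 100 for any beta — the
flip destroys the first-order dependence faster than the coefficient can
restore it. The differential-correlation signal the method demonstrably
detects (acceptance-checked at > 80% power against < 10% for the best
Bonferroni-corrected per-gene rank test) is the one where the flip is tied
to the phenotype group, i.e. the correlation structure differs *between
groups*.

## Problem sizes used in the checks

Level/type I error: collection A, categorical endpoint with 50 subjects per
group, 500 replicates (Monte-Carlo SE of a 5% rate ≈ 1%, averaged over 50
null sets). Oracle agreement: 50 random instances, n ∈ {4..25}, tolerance
1e-12. Concordance: 50 datasets, B = 10,000. Null uniformity: 2,000 pooled
null-set p-values. Driver recovery: 100 replicates of a 20-gene set with 5
planted drivers at n = 100. The `reps` warning threshold in
`estimate_level_power` enforces Monte-Carlo SE < alpha/2.
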