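# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Abundance and occupancy

**TPM normalization.** The profiling input is a read-mapping summary per
(species, sample): mapped bases, the representative-sequence length, and
the sample's total sequenced bases. The per-sample abundance is computed
as a length-normalized recruitment rate, `rate_i = mapped_bases_i /
ref_length_i`, renormalized so the sample sums to 10⁶ (TPM). The
renormalization makes the unit self-consistent and testable (per-sample
sum is exactly 10⁶ whenever anything recruited) and makes abundances
invariant to sequencing depth; the raw bases-per-length-per-total-bases
ratio differs from TPM only by a per-sample constant, so every
downstream statistic that uses compositions (Bray-Curtis, occupancy,
range size) is identical under either convention. A sample with zero
recruitment yields the zero vector.

**Occupancy classes.** A species is *present* in a region when its TPM
exceeds the presence threshold in at least one sample of that region.
The default threshold is 0 (any recruitment counts); it is configurable
because no universal detection cutoff exists. Classes: *core* = present
in every region, *endemic* = exactly one region, *intermediate* =
anything between; a species undetected everywhere at a positive
threshold is reported as *absent* rather than silently dropped. The
gene-family analogue first discards singleton KOs (annotated in exactly
one genome) as likely assembly/annotation artifacts, then classifies the
rest by the regions of their carrier genomes (*shared* / *multi-region*
/ *region-specific*).

**Range-size index.** For a species with abundance fractions f₁…f_K
across the K regions (region-summed TPM divided by the species' global
total), the index is `1 − sd(f)`, with the *sample* standard deviation
(K−1 denominator): this is the convention under which a one-hot vector
gives exactly 0.5 at K = 4 and the uniform vector gives exactly 1.0.
Region sums (not per-sample means) are used to aggregate abundance into
fractions; with unequal sample counts per region the two aggregations
differ, and region sums were chosen as the simpler, documented
convention. All-zero species are flagged and excluded.

## Distance-decay, PERMANOVA, contrasts

**DDR.** All sample pairs are formed with their great-circle distance
(haversine, Earth radius 6,371 km, WGS84 decimal degrees) and community
dissimilarity. The fit is OLS of log₁₀(similarity) on log₁₀(distance).
Similarity is 1 − d for Bray-Curtis; Euclidean distance is unbounded, so
its similarity transform is 1/(1 + d) — bounded, monotone, and
documented here precisely because the transform changes the absolute
slope (only comparisons between fits using the same transform are
meaningful). Pairs with zero distance or non-positive similarity cannot
be log-transformed and are excluded, with the exclusion count reported.
A perfectly constant response returns slope 0, p = 1 rather than NaN.

**PERMANOVA.** One-way, on the squared-distance partition: `SS_total =
ΣΣ d²/n`, `SS_within = Σ_groups Σ d²_within / n_g`, pseudo-F =
`(SS_between/(g−1)) / (SS_within/(n−g))`, `R² = SS_between/SS_total`,
and `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)` with free label
permutations (no strata — habitat is not a blocking factor here).
Permutations default to 999, so the smallest attainable p is 0.001. The
implementation is vectorized over permutations and cross-checked against
scikit-bio's PERMANOVA statistic in the test suite. A distance matrix
with no variation reports (0, 0, 1).

**Rank-sum contrasts.** Two-sided Mann-Whitney U. Exact enumeration is
used when both groups have n ≤ 8 and no cross-group ties; otherwise the
tie-corrected normal approximation with continuity correction. The
switch point keeps exactness testable while matching large-sample
behavior; by exact enumeration of the null at n = m = 7 the two paths
agree to 0.0124 in the worst case (central U values, p ≈ 0.46) and to
better than 0.01 wherever p < 0.25. Benjamini-Hochberg step-up is used
for all multiple-contrast families.

## ANI divergence

ANI values are consumed, not computed. The species tier keeps all genome
pairs; the strain tier keeps pairs with ANI ≥ 95 % (inclusive — a pair
at exactly 95.00 is strain-tier), the conventional species boundary. For
a focal region, *within* = both genomes from that region, *between* =
exactly one; the contrast is the two-sided rank-sum test, and a region
with an empty side raises an explicit insufficient-data error (this
occurs in practice: region pairs can lack strain-tier pairs entirely).
Region centroids are unweighted means of member-sample coordinates;
region-pair summaries are ordered by centroid distance descending, ties
broken lexicographically.

## The Mk transition engine

**Model.** Continent occupancy evolves along the rooted species
phylogeny as a K-state continuous-time Markov chain with generator Q,
off-diagonal rates q_ij ≥ 0, rows summing to zero. Constraints follow
the standard MultiState repertoire: every ordered pair free, rates tied
pairwise equal (q_ij = q_ji), or individual rates fixed to zero. Root
state frequencies default to uniform (1/K) and are configurable; the
root treatment is a genuine modeling choice, not an identified quantity.
Before rate inference the tree is rescaled so the mean branch length is
exactly 0.1 (one multiplicative constant, ratios preserved) — rates and
time scale are confounded, and this convention keeps rates away from
numerically tiny values.

**Tip coding.** Tips may be ambiguous: each tip carries a 0/1
compatibility vector over continents, built from per-continent relative
abundance with threshold 0.05 by default (a continent counts if it holds
≥ 5 % of the species' abundance; if none does, the argmax continent is
forced). The threshold is exposed because presence/absence versus
abundance-threshold coding is a real analysis degree of freedom.

**Likelihood.** Felsenstein pruning with per-node rescaling by the
maximum partial (log accumulated), so deep trees cannot underflow.
Transition matrices P(t) = exp(Qt) are computed by eigendecomposition,
vectorized over all edges of the tree in one pass; the longest edge is
cross-checked against scipy's scaling-and-squaring `expm` and the whole
evaluation falls back to `expm` per edge when the reconstruction error
exceeds 10⁻¹², which catches near-defective generators. Rows are
clipped to [0, ∞) and renormalized; zero-length branches are legal and
give P = I. Binary trees use a level-batched sweep (nodes grouped by
subtree height) so a 300-tip likelihood evaluation costs well under a
millisecond. Fully ambiguous tips must give likelihood exactly 1 (total
probability); this identity is run as a built-in self-test before every
MCMC run.

**MCMC.** Random-scan Metropolis-Hastings. Each free rate moves by a
multiplicative log-space random walk (with the q′/q Hastings
correction), which respects positivity without boundary handling.
Per-parameter step sizes adapt toward a 0.2–0.4 acceptance rate during
burn-in only and are frozen afterwards, preserving detailed balance for
the retained samples. Priors per free rate: uniform(0, 100),
exponential(mean 1), gamma(shape 1, scale 1), or hyper-prior versions in
which the prior's parameters are themselves extra MCMC dimensions with
uniform(0, 10) hyper-priors (the upper bound for hyper-uniform, the mean
for hyper-exponential, shape and scale for hyper-gamma). The production
chain-length convention (10,100,000 iterations, 100,000 burn-in,
sampling every 1,000, three repeated runs) is available as
`McmcConfig.paper_mode()`; the library and test default is a desk-scale
100,000/10,000/10. Across-run congruence uses the Gelman-Rubin PSRF,
floored at 1.0, with the conventional 1.1 pass threshold.

**Marginal likelihood.** Stepping-stone sampling with the Beta(0.4, 1)
quantile temperature schedule β_k = (k/n_stones)^(1/0.4), the standard
choice that crowds stones near the prior. The chain starts at the
posterior and cools; each stone samples the power posterior L^β × prior
(a short per-stone burn-in of 10 % of the stone's iterations, minimum
50, absorbs the temperature step) and contributes log mean L^Δβ; the
telescoping sum estimates log Z. Defaults are 100 stones × 1,000
iterations; the estimator is validated against direct quadrature on
one-parameter models (agreement well within 0.2 log units) and against
the identity log Z = 0 for constant likelihood, which it reproduces to
machine precision. Model comparison reports the log-Bayes factor with
|log BF| ≥ 10 labelled very strong evidence.

## Synthetic data: what it emulates, and what it does not

The community generator reproduces the *design* of a four-region,
51-sample global survey: region centroids approximating the East
African Rift Valley, Inner Mongolia, the Kulunda Steppe and the Cariboo
Plateau (inter-region distances span ~2,000–15,000 km), per-region
sample counts of 14/18/15/4, samples jittered Normal(0, 1°) around
centroids and alternating water/sediment. Species are assigned
occupancy classes with default fractions 16.3 % core / 34.5 % endemic;
each species has a home region, occupies its home region with
probability ≥ 0.7, and reaches a sample at distance d from its home
centroid with probability exp(−d / decay_scale_km) (default scale 3,000
km) — one presence per allowed region is always forced so generated
classes are recoverable exactly, which is the round-trip identity the
tests assert. Mapped bases are log-normal (μ = 10, σ = 2 on the log
scale) over representative lengths of 1.5–6 kb, and sample totals imply
a 2–10 % recruitment fraction. The ANI generator draws within-region
pairs from Normal(within_mean, sd) and between-region pairs with a mean
lowered proportionally to centroid distance, truncated to [70, 100].
Tip states evolve forward under a known Q on a Yule tree (pure birth —
the simplest branching model with known expectations; the empirical
tree's shape is not modeled).

Deliberately *not* emulated: read-level noise, assembly and binning
artifacts, phylogenetic signal in abundances, uneven detection
sensitivity between water and sediment (an optional habitat offset
exists but has no calibrated value), and the empirical skew of endemics
toward any particular region (home regions are uniform). Passing tests
therefore demonstrate that the statistical machinery recovers known
structure of this idealized design — not that real soda-lake data are
free of the upstream artifacts the generator omits.

## Problem sizes and defaults used in the checks

The self-checks run at desk scale by design: pruning is verified against
exhaustive state-space enumeration on 4-tip trees (where the 3⁷-term
brute force is feasible); stepping-stone against quadrature on 6-tip
one-parameter models (32 stones × 300 iterations); rate recovery on
300-tip trees over 20 seeds with 6,000-iteration chains under the
symmetric-rates constraint (the generating truth is symmetric), checking
that posterior medians order the fast Asia↔North-America rate above all
Africa rates and that 95 % credible intervals cover the truth;
permutation-test calibration with 800–1,000 null simulations. The MCMC
kernel itself is validated distributionally: on a two-tip, one-parameter
problem its 10⁵-sample trace matches direct grid integration of
likelihood × prior to Kolmogorov-Smirnov distance < 0.05.

## Known limitations

* Transition rates are identified only up to the tree's time scale;
  after rescaling to mean branch length 0.1 they are comparable across
  analyses of the same tree but have no absolute time units, and
  transitions cannot be dated.
* The engine assumes the phylogeny is fixed and error-free; topology or
  branch-length uncertainty is not propagated.
* Hyper-prior ranges (uniform 0–10) follow common tool convention and
  are config-exposed; posterior inferences under weak data can be
  sensitive to them.
* The functional-similarity transform for Euclidean distances is a
  package convention; absolute functional DDR slopes are not comparable
  to other tools' choices.
* PERMANOVA assumes exchangeable samples under the null; with strong
  within-region dependence (e.g. repeated sampling of one lake) the
  permutation p-value is anti-conservative.
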