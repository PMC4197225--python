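# Methods

## The generative model behind the simulator

A simulated cohort is a gene × sample matrix of log2 expression values
drawn from a three-level hierarchy. For each latent subgroup
independently:

1. per-gene mean levels `μ_g ~ Normal(μ₀, σ_g)` — σ_g (the
   *within-sample* SD) is the spread of gene levels inside one profile;
2. per-gene between-sample SDs `σ_P ~ InvGamma(α, β)` — σ_P controls how
   much one gene varies across patients;
3. observed values `X_ij ~ Normal(μ_g, σ_P)` on the log2 scale (so X is
   log-normal on the natural scale).

Defaults: `μ₀ = 8`, `σ_g = 1.5` (a low-variation alternative uses 0.5),
`α = 15`, `β = 7`, 50 genes × 40 samples per cohort. With these
hyperparameters the prior mean of the inverse-gamma draw is
`β/(α−1) = 0.5`.

**Scale of the inverse-gamma draw.** The draw is interpreted directly on
the SD scale: `σ_P ~ InvGamma(15, 7)` with mean 0.5 log2 units. An
alternative reading places the prior on the variance and takes the square
root, which would give an effective SD near `sqrt(0.5) ≈ 0.71` and make
the variance decomposition visibly biased against the stated generating
value of 0.5; the SD-scale reading is therefore the default, with
`ig_on="variance"` available as a switch.

**Latent subgroups.** Each subgroup redraws *both* the μ_g vector and the
σ_P vector with the same hyperparameters; gene identity is positional
across subgroups. Subgroups are therefore exchangeable: permuting the
group-size vector permutes the labels but not the distribution of any
diversity metric. RNG streams are spawned per group from one root seed,
so adding a group never perturbs the draws of earlier groups and
identical configs are bit-identical.

**Binarization.** Categorical benchmark profiles are obtained by
`Z = (X − M)/SD > 1.5`, where M and SD are the grand mean and the
*population* (ddof = 0) SD of the whole matrix. The grand-matrix reading
of "overall" and the population SD flavor are recorded in the output
metadata; both are conventions the thresholding rule leaves open, and
neither changes any qualitative result (the threshold crossings move by
O(1/√N) of a z-unit).

## Distance metrics

* Pearson distance uses `d = (1 − ρ)/2`, mapping the correlation range
  [−1, 1] onto [0, 1] so that all three continuous metrics share a common
  scale. The alternative `1 − ρ` is a monotone transform that changes no
  ordering; it is exposed as `scale="one-minus-rho"`.
* Cosine distance is the angle normalized by π, not `1 − cos θ`; the two
  differ in calibration, and the angle form is the one bounded exactly by
  [0, 1]. Pearson correlation equals the cosine similarity of
  column-centered vectors, an identity asserted to 1e−12 in the tests.
* Hamming distance is normalized by the panel length L by default so
  values are comparable across gene panels; raw counts are available.

## Dispersion distance

Given any pairwise distance matrix D, Gower double-centering
`G = J(−½ D∘D)J` defines the principal-coordinate embedding; the squared
Euclidean distance of sample *i* to the overall (arithmetic) centroid of
the embedded points equals `G_ii` exactly, with positive-eigenvalue axes
contributing positively and negative-eigenvalue ("imaginary") axes of a
non-Euclidean semimetric negatively. The implementation reads the
centroid distances off the diagonal rather than forming the embedding;
the eigenvalues are still computed and reported for diagnostics.

Numerical choices:

* `G_ii < 0` (possible for semimetrics) is clamped to 0; affected samples
  are listed in the result and a warning is logged. With Pearson
  distances on 40-sample cohorts this typically touches 0–3 samples and
  shifts the mean dispersion negligibly.
* Eigenvalues below `−1e−10 · max|λ|` count as genuinely negative.
* A "literal" centering variant (double-centering D itself, without the
  −½ D² step) is kept as a diagnostic only: it is not the PCoA embedding
  and its diagonal has no centroid-distance interpretation.

The mean (default) or median of the per-sample centroid distances is the
cohort's diversity. For pairwise metrics the summary runs over the
n(n−1)/2 unique off-diagonal entries only.

## Bootstrap and permutation inference

Within-group diversity is bootstrapped by drawing `group_size = 100`
samples with replacement, `n_boot = 500` times, recomputing the distance
structure on each resample. Duplicated samples are retained as coincident
points — deduplicating would bias diversity downward unevenly across
resamples. Each group's resampling stream is keyed by (seed, group name),
so results for one group do not depend on which other groups are in the
run.

Two bootstrap vectors are compared by pooling them, permuting the pool
without replacement R = 10⁵ times, and counting permutations whose
absolute difference in half-means strictly exceeds the observed one:
`p = (1 + #(D > d))/(1 + R)`, bounded below by 1/(1+R). Absolute
differences make the test two-sided and exactly symmetric in its
arguments (the pooled vector is sorted before permuting, which the
permutation law is invariant to). Under the null the p-values are
uniform, which the test suite checks with a Kolmogorov–Smirnov test over
500 repeats.

## Variance decomposition

With `m_i` the across-sample mean of gene *i* and `s_i²` its
across-sample variance (sample, ddof = 1, throughout):
`μ̂₀ = mean(m)`, `σ̂_g = SD(m)`, `σ̂_P = sqrt(mean(s²))`. On one-group
cohorts the estimators are nearly unbiased; σ̂_g carries a small upward
O(σ_P²/n_samples) term and σ̂_P reflects `E[σ_P²] = 0.25 + Var(σ_P)`
rather than `(E σ_P)²`, both well inside the ±0.1 / ±0.05 bands the
recovery study checks. Latent subgroups move variance between the
components: σ̂_P grows and σ̂_g shrinks with the number of subgroups,
which is the diagnostic signature of hidden substructure.

## Pathway de-overlap

Overlap between two gene sets is tested with the exact upper-tail
hypergeometric probability `P(X ≥ n)` (universe = union of all member
genes unless supplied). Pairs with `P < 0.05` are "similar"; the set with
the highest similarity degree is removed recursively until no similar
pairs remain. Since pairwise similarity is fixed per pair, subsetting the
similarity matrix and recomputing it coincide. Degree ties are broken by
removing the larger set (it absorbs more overlap), then the
lexicographically smallest name — a deterministic rule logged with every
removal.

## Copy-number and mutation preprocessing

Segmented log2 ratios are trichotomized with strict cutoffs
(`< −0.3` deletion, `> 0.3` amplification, boundary values "none"). A
gene inherits a sample's call only when one segment fully contains its
transcribed region on the same chromosome; straddling and uncovered genes
are "none" (regions without segment coverage are treated as "none" rather
than dropped). All intervals are normalized to 0-based half-open
coordinates internally: SEG files are read as 1-based inclusive and
shifted, BED-derived gene models are native. Strand is ignored; duplicate
transcripts collapse to the union interval per gene id. For Hamming
panels, genes altered in no sample are dropped by default for
copy-number data (this changes the normalizing L) and kept for mutation
data.

## What the simulator does and does not emulate

The generator reproduces controlled within/between-sample variation and
latent substructure — the features the diversity metrics are meant to
detect. It does not emulate gene–gene correlation blocks, batch effects,
platform noise, censored/low-expression floors, or outcome-linked
structure. Passing the simulation benchmarks therefore shows the metrics
rank cohort heterogeneity correctly under the hierarchical model, not
that they are robust to platform artifacts; on real data the recommended
practice is the built-in filtering (drop the lowest expression quartile,
then the lowest MAD decile, with genes exactly at a cutoff kept) and
batch correction upstream of this package.

## Problem sizes used in the checks

The recovery study uses 500 replicate cohorts of 50 × 40 per scenario;
monotonicity of the metrics across 1/2/4/40 latent subgroups and across
minority-group proportions is averaged over 200 seeds per condition;
permutation-test calibration uses 500 repeats at R = 999 and the floor
check runs at the full R = 10⁵. These sizes give Monte-Carlo standard
errors an order of magnitude below the effects being checked.

## Known limitations

* Pearson and cosine distances are semimetrics; triangle-inequality
  based reasoning does not apply, and the dispersion embedding can carry
  negative eigenvalues (handled by clamping, reported).
* The permutation test assumes the two bootstrap vectors are
  exchangeable under the null; comparing groups of very different sizes
  with the same `group_size` can make the bootstrap distributions
  differently concentrated.
* The de-overlap reduction is greedy; it finds *a* minimal-overlap
  collection, not a globally optimal one, and the surviving count can
  depend on the tie rule when many degrees coincide.
* Gene-identifier spaces are not translated; matrices, gene sets and
  gene models must share an id space.
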