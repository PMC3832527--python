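# Methods

This note records the statistical model behind `tagdge`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Count model and the two-step test

Tag counts Y_{g,r} (gene g, library r) are treated as overdispersed
Poisson on the quasi-likelihood scale: with depth-normalised counts
z_{g,r} = Y_{g,r}/s_r, the working model is E(z) = λ_g and
Var(z) = φ_g·λ_g. φ = 1 recovers Poisson; φ > 1 captures biological
variability between replicate libraries. The procedure assumes (i) most
genes are not differentially expressed and (ii) genes of similar mean
expression have similar dispersion.

**Step 1.** A common-mean model (no condition term) is fitted per gene
across all R replicates of both conditions, giving the moment estimator

    λ̂_g = mean_r(z_{g,r}),
    φ̂_g = Σ_r (z_{g,r} − λ̂_g)² / ((R−1)·λ̂_g).

Pooling conditions is deliberate: under assumption (i) it is harmless
for most genes, and for truly DE genes it *over*-estimates φ, which
lowers power slightly but cannot inflate the Type-I error. Genes with
zero counts in every library carry no information: they are flagged
untestable, excluded from smoothing and testing, and never counted in
the multiple-testing denominator.

**Smoothing.** φ̂_g is noisy at R = 4 (three denominator degrees of
freedom), so it is replaced by the Loess fit of φ̂ on x = log₁₀ λ̂,
evaluated at each gene and clamped from below. Choices:

- *Local degree 2, tricube weights, no robustness iterations.* Degree 2
  because the empirical mean–dispersion trend of tag data is close to
  quadratic in log-mean; a local quadratic reproduces a global quadratic
  exactly (a property the tests enforce), a local linear fit does not.
- *Span* (fraction of genes per window): default **0.3**. Small enough
  to track curvature over four decades of expression, large enough that
  each window averages thousands of genes in a genome-scale run.
- *x-axis = log₁₀ mean* so windows are balanced across the expression
  range, which spans orders of magnitude.
- *Floor* on the smoothed φ̃: default **1.0**, the Poisson bound.
  Scaling the step-2 statistic by φ̃ < 1 would anti-conservatively
  inflate it; the floor is configurable down to 1e−8 for data known to
  be underdispersed.
- Degenerate windows (all x identical) fall back to the mean of the
  tied points; with a single shared mean this reduces to the global
  mean of φ̂.

A global quadratic least-squares fit of φ̂ on (1, x, x²) is provided as
a diagnostic companion curve, plus a per-gene table (log₁₀ mean, raw,
smoothed, quadratic fit) for plotting the mean–dispersion trend.

**Step 2.** Condition means are the ML estimates under a Poisson
likelihood on the normalised counts, λ̂_c = mean of z over the
replicates of condition c, and the contrast H₀: λ_G = λ_M is tested by
the scaled deviance

    T_g = 2·[ℓ(λ̂_G, λ̂_M) − ℓ(λ̂_0)] / φ̃_g,  ℓ(λ) = Σ_r (z_r ln λ − λ),

referred to χ² with 1 df (a quasi-LRT with plug-in dispersion, not an
F-test: φ̃ is estimated from thousands of genes and treated as known).

*Why the likelihood is written on the normalised scale.* Step 1's
dispersion, the consistency filter, and the reported condition means
all live on z = Y/s. Evaluating the step-2 likelihood on the same scale
keeps one dispersion scale throughout and makes every statistic exactly
invariant to rescaling a library's counts together with its size factor.
When size factors are equal — the design case for this pipeline, where
library sizes are nearly identical — the fit coincides with the
count-scale likelihood with offsets. With strongly unequal depths the
two differ (the offset fit weights deep libraries more); this package
intentionally uses the unweighted normalised-scale form.

**Multiple testing.** Benjamini–Hochberg step-up over the testable
genes; a gene is called DE when q ≤ α (boundary inclusive), default
α = 0.05. m equals the number of testable genes after exclusions, not
the raw gene count.

**Consistency filter.** A gene called up in condition A keeps DE status
only if its replicates are consistently higher: default (`minmax`) the
smallest normalised A replicate must strictly exceed the largest B
replicate. This is the stricter reading of "each replicate consistently
greater"; a `pairwise` mode (r-th vs r-th replicate) exists behind the
config switch, but since replicates of the two conditions have no
natural pairing the min/max form is the default. Filtered genes keep
their p and q values; only the DE call is withdrawn, so the filter can
only reduce the false-discovery proportion. The pipeline summary always
satisfies post-filter DE = pre-filter DE − filtered and up₁ + up₂ =
pre-filter DE.

**Gene exclusion.** An optional pre-analysis step removes genes
annotated to configured GO terms (e.g. an immunity category confounded
by contamination of one sampling site), before dispersion estimation so
excluded genes influence nothing downstream.

**Normalisation.** Default size factors are `total-count`: column total
over the geometric mean of column totals (factors multiply to 1). With
near-equal library sizes this is a minimal, faithful choice; `none`
disables normalisation entirely.

## Genomic clustering test

Statistic: for each selected gene, the distance from its midpoint to
the nearest other selected gene's midpoint *on the same chromosome arm*;
the statistic is the mean over selected genes that have a within-arm
neighbour. Genes alone on their arm are excluded from the average;
cross-arm distance is undefined (treated as infinite). Midpoints (not
starts) anchor the distance; both conventions are defensible, midpoint
is symmetric under strand and interval length.

Null distribution: B draws (default 10,000) of equally many genes,
uniformly without replacement from the analysed universe. p-value:
add-one estimator p = (1 + #{null ≤ observed})/(B + 1) — never exactly
zero, ties count as at-least-as-clustered. An exhaustive mode enumerates
all C(n, k) subsets for small universes and returns the exact
probability; Monte Carlo and exhaustive agree within binomial error.
The natural selected set is the pre-consistency-filter DE list (the
larger, unpruned set); this is configurable.

The Monte Carlo p is discrete on (B+1) equiprobable atoms. Calibration
is therefore checked by a chi-square goodness-of-fit over atom-aligned
bins rather than a continuous-uniform KS comparison, which would be
biased by the discreteness.

## GO over-representation

One-sided hypergeometric upper tail per term: P(count ≥ N) for N query
hits among X term members, with the universe restricted to genes
carrying at least one annotation (the convention of genome-background
enrichment tools), then BH across terms. This is a transparent
Fisher-test stand-in for resampling-based enrichment services: rankings
agree in practice but p-values are not numerically comparable to tools
using a different correction. No GO-graph ancestor propagation is done;
pre-propagated annotation tables are accepted as-is.

## Allele frequencies

Diploid genotype counts collapse to allele counts k = 2·hom + het of
n = 2·individuals (autosomal locus; males are diploid carriers). The
95% interval is exact Clopper–Pearson from beta quantiles:
lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k), with the k = 0
and k = n boundaries pinned at 0 and 1. Exact intervals are
conservative — coverage ≥ nominal for every true frequency — which the
test suite verifies by simulation. Wilson or Wald intervals would give
visibly different bounds at the near-fixed and near-absent frequencies
this tool is typically used at.

## Synthetic data

The generator emulates exactly the structure the analysis assumes:

- Gene means λ_g log-normal (default location ln 100, scale 1 — a
  realistic spread of four decades for genome-scale tag counts).
- Dispersion trend φ(λ) = 1 + λ/k with default **k = 100** (φ ≈ 2 at
  the typical mean, rising with expression), optional multiplicative
  log-normal noise, floored at φ = 1 (no underdispersion is generated).
- Counts: negative binomial parameterised by Var = φ·mean (size
  r = μ/(φ−1)) when φ > 1, Poisson when φ = 1; per-sample size factors
  scale the mean.
- Design: two conditions × two replicates by default, configurable.
- DE genes: a fraction (default 5%) receive a fold change (default
  |log₂FC| = 2, random sign) applied to the second condition; the truth
  table records flags, fold changes, per-condition means and φ.
- Gene maps: positions uniform over arms proportional to arm length
  (default template: the six major *Drosophila* arm lengths), with an
  optional subset forced into one window of configurable width to
  create genuine clustering.
- GO annotations: random subsets per term, with an optional spiked term
  forced to a chosen overlap with a chosen query.
- Genotypes: multinomial Hardy–Weinberg proportions (p², 2pq, q²).

Every generator takes an explicit seed and is bit-reproducible; there
is no global random state.

What it does *not* emulate: raw reads, mapping error, 3′ coverage bias,
ortholog mis-assignment between sibling species, tandem gene families,
or correlated annotation structure. Passing tests therefore demonstrate
the statistics are implemented correctly and calibrated under the
model's own assumptions — not that those assumptions hold for any
particular real dataset.

## Numerical conventions and problem sizes

- Coordinates are BED: 0-based, half-open; strand is read but unused.
- 0·ln 0 = 0 in likelihoods; T is clipped at 0 against rounding.
- All file formats are UTF-8 TSV/BED/JSON with LF endings; readers
  validate and reject rather than coerce.
- The FDR-control validation runs ten replicate simulations of 10,000
  genes (2×2 design): large enough that each run yields ~500
  discoveries, so the per-run false-discovery proportion is estimated
  from a few hundred calls, while the whole check completes in well
  under a minute.
- Calibration checks use 500 trials at B = 199 (clustering) and 2,000
  draws (CI coverage); the Loess window minimum is degree + 2 points,
  and spans outside (0, 1] are rejected.

## Known limitations

- Two conditions only; no multi-factor designs or interaction terms
  (medium effects are addressed only via the consistency filter).
- The quasi-LRT treats φ̃ as known; with very few genes the smoothed
  dispersion is itself noisy and the χ² reference is approximate.
- The consistency filter is heuristic (no error-rate guarantee beyond
  never increasing the FDP).
- Enrichment p-values are Fisher/hypergeometric, not comparable to
  resampling-corrected services.
- With strongly unequal library depths the normalised-scale likelihood
  underweights deep libraries relative to an offset GLM fit.
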