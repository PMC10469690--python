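# Methods

This note documents the statistical models implemented in `bgconserve`,
the conventions chosen where the literature leaves room, and what the
synthetic-data generator does and does not emulate.

## Trees and distances

Trees are rooted, branch-length-bearing phylogenies over uniquely
labelled tips, parsed from newick with dendropy (internal labels and
bootstrap values tolerated and ignored; quoted labels supported) and
held in flat postorder-indexed arrays for vectorised traversals. Branch
lengths are required; `assume_unit_lengths=True` substitutes 1.0
everywhere for cladograms. Rooting is taken as given — no automatic
outgroup rooting is attempted, since published trees arrive rooted by
the authors' own conventions.

Zero-length branches are retained as distances; any statistic that
divides by a branch length (contrast weights) substitutes
ε = 1e-8 (`core.ZERO_BRANCH_EPS`). Polytomies are resolved by repeatedly
joining two randomly chosen children under a new zero-length edge
(seeded, reproducible); this leaves every tip-to-tip distance unchanged
while giving the contrast machinery the strictly bifurcating tree it
needs.

The cophenetic matrix holds tip-to-tip path lengths; the shared-path
matrix C (used by Pagel's λ) holds root-to-LCA path lengths with tip
depths on the diagonal. Both are computed in a single postorder merge,
O(n²) overall.

## Fritz–Purvis D

For a binary trait, a postorder sweep accumulates |x_L − x_R| at every
internal node, where child values are replaced by their
branch-length-weighted average and the parent-side branch is lengthened
by b_L·b_R/(b_L + b_R) — standard Felsenstein contrast bookkeeping with
*unstandardised* differences. The branch-length adjustment is
trait-independent, so it is precomputed once and the sweep runs on an
(n_tips × k) matrix of trait columns; a 1000-permutation test on a few
hundred tips takes well under a second.

Two Monte-Carlo nulls condition on the observed prevalence m:

- *random*: uniform shuffles of the tip labels;
- *Brownian*: Brownian motion simulated along the tree (root 0, rate 1,
  Normal(0, branch-length) increments), each replicate thresholded so
  exactly the m top-valued tips become 1 (ties broken by row order).

`D = (d_obs − mean d_BM) / (mean d_rand − mean d_BM)`, so E[D] = 1 under
the random null and E[D] = 0 under the Brownian null by construction —
the calibration the acceptance script verifies empirically.

Tail conventions (the original description leaves them implicit):
`p_random = (1 + #{d_rand ≤ d_obs}) / (n_perm + 1)` and analogously for
`p_brownian`. The "≤" direction makes a small p mean "at least this
clumped", matching the interpretation that low D = strong conservation;
the +1 correction keeps p in (0, 1] with minimum 1/(n_perm+1). Both null
vectors are stored on the result so users can recompute either tail.

## Pagel's λ

Counts are used directly as the continuous trait (a `log1p` flag is
available but off by default; published analyses of BGC counts feed the
raw table). The model is x ~ MVN(μ1, σ²C(λ)) with C(λ) multiplying the
off-diagonal of C by λ. μ and σ² are profiled in closed form via a
Cholesky solve, leaving a 1-D bounded maximisation of the profile
likelihood over λ ∈ [0, 1]; the optimiser's answer is compared against
both boundary values explicitly, since a boundary maximum can defeat
golden-section search. The upper bound is fixed at 1 (the common
default) rather than the matrix-feasibility maximum. Significance is the
χ²(1) upper tail of LR = 2(lnL(λ̂) − lnL(0)); when λ̂ = 0 the LR is 0
and p = 1. A tree whose structure makes C(λ) singular (for example
duplicated zero-depth tips) raises an informative error.

## consenTRAIT τ_D

Qualifying clades are the *maximal* internal nodes with ≥ 2 descendant
tips whose fraction of trait-positive tips is ≥ `min_fraction` (default
0.9); maximality means no qualifying ancestor. Clade depth is the mean
path length from the clade's root node to **all** its descendant tips
(positive and negative alike; at min_fraction = 0.9 the alternative
positive-only average differs by at most the 10% minority and is
selectable with `depth_over_positive_only=True`). Positive tips outside
every qualifying clade are singletons; with `count_singletons=True`
(default) each contributes the constant `singleton_depth` (default 0) to
the depth set. τ_D is the unweighted mean of that set (`weighted=True`
weights clades by tip count, singletons by 1); τ_min/τ_max are its
extremes. A half-terminal-branch singleton convention
(`singleton_half_branch=True`) is available for cross-checks against
older trait-depth descriptions.

Significance permutes tip labels uniformly: conserved traits produce
large τ_D, so `p = (1 + #{τ_perm ≥ τ_obs}) / (n_perm + 1)` (upper tail;
the full null vector is stored so the opposite tail is recoverable).
The permutation null is computed for all columns at once by a vectorised
postorder count of positive tips per node; the observed statistic is
additionally computed by an explicit per-clade path, and the two must
agree — a brute-force enumeration oracle (`consentrait_oracle`, trees
≤ 14 tips) pins both down in the tests.

Fractions are compared with a 1e-9 guard so that 0.9 × 10 does not fail
against 9 positive tips through floating-point representation.

## Community structure

Bray–Curtis is computed with scipy's pairwise machinery; pairs of
all-zero profiles (0/0) are set to 0 with a warning rather than
propagating NaN. Mantel correlates the lower-triangle entries (Pearson
by default, Spearman by flag) and permutes one matrix's rows/columns
jointly, one-sided upper tail. PCoA is Gower double-centering
B = −½·J·D²·J followed by symmetric eigendecomposition; coordinates are
eigenvectors scaled by √eigenvalue for positive eigenvalues, and
negative eigenvalues are reported, not corrected. PERMANOVA uses the
distance sum-of-squares decomposition (SS_total = Σ_{i<j} d²/n,
SS_within per group) with free label permutation — no strata, since the
analyses this supports state no blocking. These three are implemented
directly on arrays because the result contracts include the null
vectors, the SS decomposition and uncorrected eigenvalues; scikit-bio's
implementations serve as independent cross-checks in the test suite.
Group ellipses are parametric: per-group mean and covariance of two
ordination axes with half-axes √(χ²₂(mass)·eigenvalue) — numbers only,
no plotting dependency.

## Genus enrichment

Per class, counts follow NB2 with a genus-only log-linear design, the
reference genus absorbed into the intercept; dispersion is estimated
jointly by ML (statsmodels). With this design the fitted genus means are
the sample means (sufficiency), which the tests exploit as a closed-form
check. Genera under `min_group_size` (default 5) genomes are pooled into
"other" — they stabilise the dispersion estimate but are excluded from
the report. Intervals are 95% Wald on the linear predictor, transformed
to log₁₀; p-values are Wald tests of the genus contrast. When the ML
dispersion indicates Poisson-like data (θ > 1e6) or the NB fit fails,
the model falls back to a Poisson GLM and says so in the result. The
negative binomial is hard-coded as the count model (with that Poisson
limit); distribution selection by AIC/residual diagnostics is a
modelling step upstream of this package. A Benjamini–Hochberg column is
emitted for information; significance calls use the raw p, matching the
reporting convention of the summaries this reproduces.

## Synthetic data

`sim_tree` implements the Yule process directly (exponential waiting
times at rate b·k, uniform lineage choice, a final waiting time so
pendant branches stay positive) so that one seed yields a byte-identical
newick string; birth–death trees are delegated to dendropy's simulator.
Binary traits come in three constructions matched to the statistics'
nulls: `random` (exact prevalence, uniform placement),
`brownian_threshold` (BM tip values dichotomised at the prevalence), and
`clade_seeded` (disjoint clades whose mean node-to-tip depth is closest
to a target depth, filled until the prevalence is reached, then 5% label
noise by default — enough to exercise the 90% threshold while keeping
seeded clades qualifying with high probability). Counts are
NB(mean_genus, θ) draws multiplied by the binary trait, so absent traits
are structural zeros; θ defaults to 2 (strong overdispersion, as BGC
counts show) and the default prevalence 0.3 reflects that most BGC
classes are present in a minority-to-half of genomes. Taxonomy labels
are mapped onto nested monophyletic clades by recursively splitting the
largest clade, giving genus ⊂ class ⊂ phylum as in real taxonomies.

One global seed expands into per-stage substreams through
`SeedSequence([seed, stage, index])` (stage 0 tree, 1 traits, 2 counts),
so each stage is independently reproducible and testable.

What the generator does **not** emulate: horizontal transfer (traits
spread only by descent or noise), correlated presence across classes,
genome-size or completeness effects on counts, MAG-specific missingness,
and within-class BGC architecture. Passing recovery tests therefore
demonstrate that the statistics measure what they claim under
tree-generated signal — not that real BGC tables are free of those
complications.

## Problem sizes and numerical choices

Default `n_perm` is 1000 everywhere, overridable per call. The
calibration and recovery suites use 256-tip trees with 500 traits at
n_perm = 200 (D), 200-tip trees with 200 replicates (λ), 500 random
trees of ≤ 12 tips (oracle equivalence), 1000 null datasets of 30
observations (PERMANOVA type I), and 100 seeds at 256 tips for the
end-to-end ranking — sizes at which the Monte-Carlo error is comfortably
inside the asserted bands while a full run stays around a minute.
Display rounding is 4 decimals; machine outputs keep full precision.
Permutation p-values always use the +1 correction. Ties in the Brownian
threshold are broken by row order; ties in top-genus selection
lexicographically. Degenerate inputs fail loudly: constant traits (D, λ
undefined), all-zero traits (τ_D undefined), zero-variance distance
triangles (Mantel undefined), single-group PERMANOVA.

## Known limitations

- D is defined here for binary traits only; Blomberg's K and discrete-λ
  are out of scope.
- τ_D max/min are reported across clades within a trait (the natural
  reading when a single tree is analysed); cross-dataset extrema are a
  tabulation concern left to the caller.
- The λ fit assumes a single trait; no multivariate or measurement-error
  extensions.
- PERMANOVA assumes exchangeable observations under the null; with
  strong phylogenetic autocorrelation its p-values are anti-conservative,
  which is one reason the Mantel test against the phylogeny is reported
  alongside it.
- Enrichment uses no genome-size or completeness covariates; with MAGs
  of varying completeness the genus contrasts absorb completeness
  differences.
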