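# bgconserve

Phylogenetic conservation analysis of biosynthetic gene cluster (BGC)
profiles.

Microbial genomes encode their specialised metabolites in BGCs, which
genome miners summarise as a genomes × classes count table (NRPS, RiPPs,
terpenes, aryl polyenes, ...). A recurring question in comparative
genomics of plant- and soil-associated bacteria is whether those
biosynthetic repertoires are *phylogenetically conserved* — do related
lineages share BGC classes more than chance, and how deep in the tree
does that sharing reach? `bgconserve` answers this for any rooted tree
plus count table, using the field's standard statistics:

- **Fritz–Purvis D** (binary presence/absence): the observed sum of
  sister-clade differences *d*obs scaled between its expectations under
  tip shuffling and under threshold-dichotomised Brownian motion,
  `D = (d_obs − mean d_BM) / (mean d_rand − mean d_BM)`. D ≈ 1 for a
  random trait, D ≈ 0 for Brownian clumping; lower D = stronger signal.
  Significance from both Monte-Carlo nulls (P_random, P_Brownian).
- **Pagel's λ** (counts as a continuous trait): the ML multiplier on the
  off-diagonal of the Brownian covariance matrix C (shared root-to-node
  path lengths), λ ∈ [0, 1], with a χ²(1) likelihood-ratio test against
  λ = 0.
- **consenTRAIT τ_D** (binary): the mean depth (root-of-clade to tips)
  of the maximal clades in which ≥ 90% of tips carry the trait, with
  singletons counted at depth 0 and tip-permutation significance.
- **Community structure**: Bray–Curtis profile dissimilarity, Mantel
  correlation with cophenetic distance, PCoA ordination, PERMANOVA over
  taxonomic groups, per-group probability-mass ellipse parameters.
- **Genus enrichment**: per class, a negative-binomial model
  `log μ = β₀ + β_genus` reporting log₁₀ fitted mean counts per genome
  with 95% Wald intervals against a reference genus.

A synthetic-data module (`bgconserve.synthgen`) generates Yule or
birth–death trees, binary traits with known signal (random placement,
Brownian threshold, clades seeded at a target depth) and overdispersed
counts with genus-level means, so every statistic can be checked by
parameter recovery without downloading genomes.

## Worked example

```python
from bgconserve import ClassSpec, SimConfig, run_conservation, simulate

cfg = SimConfig(
    n_tips=128, seed=31, n_genera=8,
    classes={
        "random_class": ClassSpec(prevalence=0.35, signal_mode="random"),
        "conserved_class": ClassSpec(prevalence=0.35,
                                     signal_mode="clade_seeded",
                                     target_depth=0.5),
    },
)
tree, table, truth = simulate(cfg)
print(run_conservation(tree, table, n_perm=500, seed=32).rounded(4).to_string())
```

prints

```
                   d_obs       D  p_random  p_brownian  lambda_hat      LR  p_lambda  tau_mean  tau_min  tau_max   p_tau sig_D sig_tau
random_class     45.1302  1.0523    0.6447      1.0000      0.0000  0.0000    1.0000    0.0151      0.0   0.3237  0.9062   0.0     0.0
conserved_class  29.9508  0.3666    0.0020      0.9441      0.0888  1.1087    0.2924    0.1278      0.0   0.4984  0.0100   0.0     1.0
Average          37.5405  0.7095    0.3234      0.9721      0.0444  0.5544    0.6462    0.0715      0.0   0.4110  0.4581   NaN     NaN
```

The class seeded into deep clades shows low D (strong signal, P_random =
0.002) and a τ_D an order of magnitude above the random class, which sits
at D ≈ 1 with no significant depth. The final `Average` row is the
unweighted mean over classes — the per-dataset summary used when
comparing genome collections (e.g. plant vs soil isolates and MAGs).

More narrative examples live in `examples/` (signal strength, trait
depth, community structure, enrichment, full pipeline); each prints its
numbers with a note on what they mean.

## Command line

```bash
conserve simulate --out sim/ --n-tips 256 --seed 1
conserve run --tree sim/tree.nwk --counts sim/counts.tsv \
             --meta sim/metadata.tsv --out results/ --n-perm 1000 --seed 42
```

`conserve run` writes `conservation_table.tsv`, `community_stats.tsv`,
`ordination.tsv`, `enrichment.tsv`, `presence_rings.tsv` and a
`manifest.json` recording every derived seed and statistical convention,
so a run is reproducible bit for bit.

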