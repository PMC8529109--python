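# Methods

## The analysis in brief

The package studies a *directed* (nonrandom) extinction scenario on
metagenome annotation data. The unit of data is a joint record
(sample, genus, phylum, function, level1–level3, hits): every functional
hit is keyed to the genus that carries it. Phyla are ranked by pooled
relative abundance across the whole corpus, and nested retention sets keep
only the top *k* phyla (defaults *k* = all, 8, 5, 2, 1 — the least-abundant
phyla go extinct first, leaving dominant "winners"). Filtering the joint
records by retained phylum simultaneously determines the surviving
taxonomic *and* functional profiles, which is the contract that makes the
taxonomy/function comparison meaningful: at every level the function-table
total N equals the taxonomy-table total N, because both count the same
surviving records.

All abundance comparisons are made on per-sample relative abundance
(each sample row divided by its own total at the projected level), so a
level's functional profile renormalizes over surviving records only and
sequencing-depth differences between samples drop out.

## Beta-diversity statistics

`funcstab.betadiv` implements the multivariate machinery directly:

- **Bray–Curtis**: D(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ); a pair of all-zero rows
  gets D = 0 by convention (logged). Similarity % = 100(1−D).
- **PCoA**: Gower double-centering of −½D², symmetric eigendecomposition,
  coordinates = eigenvector·√max(λ,0). Negative eigenvalues (possible for
  non-Euclidean dissimilarities) are reported but excluded from the
  percent-variation denominator, which therefore sums to 100 over positive
  axes. Axis signs are fixed by making the largest-magnitude loading
  positive, so output is deterministic.
- **PERMANOVA** (one factor): SS_total = (1/N)Σ_{i<j}d²ᵢⱼ,
  SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d²ᵢⱼ, pseudo-F =
  (SS_between/(a−1))/(SS_within/(N−a)), R² = SS_between/SS_total. The null
  is built by unrestricted permutation of group labels (the conventional
  one-factor scheme); the p-value uses the (1+b)/(1+m) estimator so p = 0
  never occurs. Because the same underlying samples appear once per loss
  level, the design is technically repeated-measures; a block-permutation
  option (`blocks=` argument) restricts shuffling to within-sample blocks
  for users who prefer the stricter exchangeability assumption. The
  default follows the conventional one-factor treatment.
- **Pairwise tests**: pseudo-t = √(two-group pseudo-F) on each pair's
  sub-matrix; unadjusted by default (Bonferroni/Holm available) to match
  the way multivariate-ecology packages conventionally report them.
- **Pearson**: product-moment r with a two-sided t-approximation p-value.

No square-root or other pre-transformation is applied before Bray–Curtis;
the standardization is relative abundance only.

## Function-specific responses

Level-1 categories partition the function hierarchy. Two dominance
cutoffs are exposed: mean relative abundance > 1 % for the trend/heatmap
panel and > 0.5 % for the statistics panel. Per category the package
reports (i) the mean relative abundance per loss level, (ii) classical
one-way ANOVA F of its per-sample abundance against loss level, and
(iii) PERMANOVA of its *internal* composition — member functions
renormalized to sum to one within the category per sample — which is by
construction invariant to the category's overall share. "Normalized
relative abundance" for the heatmap is the per-category z-score across
loss levels (a min–max variant can be obtained by rescaling the trend
matrix before clustering); row distance is 1 − Spearman rank correlation
with average ranks for ties, clustered by average linkage (UPGMA). A
constant row has undefined rank correlation and is assigned the maximal
distance 2 to every other row, with a log entry.

## Co-occurrence networks

Features (genera for taxonomy, level-3 categories for function) are kept
if present in strictly more than half of the samples; remaining zeros are
filled with pseudo-abundance 0.01 and values are log₁₀-transformed, so an
absence maps to −2. Pearson correlations among features form the
similarity matrix; |r| ≥ S_t defines an undirected edge whose sign is
sign(r) — thresholding on |r| with the sign retained is required for the
negative-link statistics to exist. The threshold is either fixed
(default 0.8) or scanned upward over 0.30–0.99: at each candidate the
eigenvalue nearest-neighbour spacing distribution of the thresholded
adjacency is compared by chi-squared fit to the Poisson law e^(−s)
(independent levels, the signature of modular structure) versus the
Wigner surmise (πs/2)e^(−πs²/4) (level repulsion, correlated noise); the
smallest candidate preferring Poisson is returned, with fully degenerate
spectra counted as Poisson since spacing mass at zero is level clustering.
This scan is a documented alternative to the proprietary default of the
molecular-ecological-network pipeline, whose exact ordering heuristic is
not published; the fixed method is the reproducibility workhorse.

Modules are greedy (Clauset–Newman–Moore) modularity communities of the
unsigned, unweighted graph; isolated features are excluded from the node
set; geodesic distance is averaged over connected pairs only (component
count is reported alongside). Edge/node exports are lexicographically
sorted Cytoscape-loadable TSVs.

## Synthetic communities

The generator emulates the statistical structure of a soil shotgun
metagenome corpus. Generative model (fixed contract, seeded NumPy
Generator):

1. phylum relative abundances ∝ decay^rank (geometric long tail);
2. within-phylum genus composition ~ symmetric Dirichlet(1);
3. genus function profile π_g = ρ·π_core + (1−ρ)·π_g,specific, both
   symmetric Dirichlet(0.5) over the function set — ρ (redundancy) is the
   weight of the shared core profile;
4. per sample, genus abundances are jittered by i.i.d. log-normal(0, σ)
   factors and renormalized;
5. counts per (sample, genus, function) cell are Poisson with mean
   depth × genus_abundance × π_g[function] (Poisson rather than
   multinomial for cell-wise independence; depth is expected, not exact).

Defaults — 40 samples, 10 phyla × 12 genera, 150 functions in 10 level-1
categories, ρ = 0.9, decay = 0.6, depth = 5·10⁴, σ = 0.5 — are chosen as a
desk-scale corpus with a realistic dominance structure (top phylum ≈ 40 %
of the community, top-2 ≈ 65 %) and moderate between-sample heterogeneity;
sequencing depth is scaled to keep the whole analysis fast while leaving
Poisson noise well below the between-sample dispersion. `ground_truth`
exposes the latent shares and profiles so tests can assert recovery
(ranking recovery at high depth; at ρ = 1 the pooled function profile is
invariant to any phylum removal up to counting noise; at ρ = 0 removal
measurably shifts it).

What the generator does **not** emulate, and hence what passing tests do
not establish about real data: real taxon/function label semantics,
between-study sample-size imbalance, spatial or biome covariates,
ecological co-occurrence structure between genera (noise factors are
independent, so synthetic networks reflect compositional and sampling
correlation only — network stages are exercised for correctness, not for
ecological realism), and any systematic association between a function
category's abundance and the number of genes it contains (level-1
categories are equal-width by construction, so the abundance–response
correlation has no built-in positive sign here). The group factor for
PERMANOVA is created by concatenating loss levels — loss level is the one
factor, with no site/biome factor simulated.

## Numerical and design choices

- Ranking ties are broken lexicographically; rankings use pooled hits
  across all samples (one shared level design for the corpus), and
  corpus-level richness S counts features with pooled hits > 0.
- Unclassified genus/function records are retained under sentinel labels
  and counted in N (conservation of hits), excludable via
  `LinkedProfile.drop_unclassified`.
- Duplicate (sample, genus, function) rows are summed at read time; reads
  are row-order independent; numbers are written with ≥ 10 significant
  digits.
- PERMANOVA permutations are drawn as whole label permutations from a
  seeded generator and evaluated vectorized; seeded runs are
  bit-reproducible.
- The pipeline writes a manifest with a config fingerprint (SHA-256 over
  the canonicalized config, excluding the output directory), seed, package
  version and per-file checksums; identical config + seed ⇒ byte-identical
  bundles.
- Alternative extinction orderings (genus-level ranking, random loss) are
  natural extensions; the implementation ranks at the phylum level, the
  scenario the pipeline is built around.

## Problem sizes

Routine tests run on small communities (≤ 10 phyla, ≤ 150 functions,
≤ 40 samples) and the headline decoupling experiment uses 20 seeded
replicates of the default 40-sample corpus at ρ = 0.9 and ρ = 0.0 with 999
permutations — sizes chosen so the full suite and the acceptance script
each complete in minutes on one CPU while keeping Monte-Carlo error well
inside the asserted margins.

## Known limitations

- The RMT threshold scan uses a simple unfolded-spacing chi-squared test;
  it is a heuristic, not a formal model-selection procedure.
- PERMANOVA assumes exchangeability under the free permutation scheme;
  with heterogeneous dispersions the test confounds location and spread
  (no PERMDISP companion is provided).
- Taxonomy is a two-level hierarchy (phylum → genus) in the canonical
  format; intermediate ranks are out of scope.
- `CommunitySummary` applies to count tables only; relative-abundance
  tables are rejected because N would be meaningless.
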