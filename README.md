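# funcstab

Directed biodiversity-loss simulation for shotgun-metagenome profiles:
does microbial **function** stay stable while **taxonomy** collapses?

Global change replaces diverse communities with a few dominant "winners"
(biotic homogenization). Because soil microbes are highly functionally
redundant, the community's functional profile may persist even when most
taxa disappear. `funcstab` quantifies that decoupling *in silico*: it takes
a joint taxonomy × function annotation table (per-sample hit counts keyed
by genus, with each genus assigned to a phylum and each functional gene to
a 3-level category hierarchy), removes phyla sequentially in ascending
order of abundance (the least-abundant go extinct first, mimicking the
elevated extinction risk of rare taxa), and measures, at each loss level:

- **Community size** — richness *S* (features with pooled hits > 0) and
  individuals *N* (total hits), for genus-level taxonomy and function-level
  annotations, with percent reductions and linear trends (Pearson *r*²).
- **Beta-diversity** — pairwise Bray–Curtis dissimilarity
  *D(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)* on relative abundances, PCoA ordination,
  and one-factor PERMANOVA (pseudo-*F*, permutation *p*, variance explained
  *R*²) with pairwise pseudo-*t* tests, loss level as the factor. If
  function is decoupled from taxonomy, the loss factor explains far less
  functional than taxonomic variation.
- **Function-specific responses** — per-category abundance trends, one-way
  ANOVA *F*, PERMANOVA of each category's internal (renormalized)
  composition, correlation of response with abundance, and average-linkage
  / Spearman-distance clustering of the category × level trend matrix.
- **Co-occurrence networks** — prevalence-filtered, log₁₀-transformed
  Pearson correlation networks thresholded at a similarity cutoff *S_t*
  (fixed, or chosen by a random-matrix-theory eigenvalue-spacing scan),
  with signed edges, greedy-modularity modules and the standard index
  panel (nodes, links, connectivity, clustering, geodesic distance,
  modularity, % negative links), exportable to Cytoscape.

The Bray–Curtis / PCoA / PERMANOVA machinery is implemented from first
principles in `funcstab.betadiv` and validated in the test suite against
exhaustive permutation enumeration, classical ANOVA equivalence and
scikit-bio.

A seeded synthetic-community generator (`funcstab.synthetic_data`)
provides corpora with a geometric phylum rank-abundance distribution,
Dirichlet within-phylum genus composition, and per-genus function profiles
mixing a shared core with genus-specific draws under a tunable
**redundancy** weight ρ — the knob that makes functional stability a
testable prediction rather than an assumption.

## Worked example

```python
import funcstab as fs

config = fs.RunConfig(
    out_dir="demo",
    synthetic=fs.SyntheticConfig(seed=1),   # 40 samples, 10 phyla, rho=0.9
    permutations=999,
    seed=1,
)
manifest = fs.run(config)
print(manifest["summary"]["permanova_taxonomy"])
print(manifest["summary"]["permanova_function"])
```

prints (numbers from this exact run):

```
{'pseudo_F': 81.58058352068241, 'R2': 0.6259511874872887, 'p': 0.001}
{'pseudo_F': 5.843260452362696, 'R2': 0.10703263377100258, 'p': 0.001}
```

Removing 9 of 10 phyla drives a taxonomic collapse the loss factor
explains 62.6 % of genus-level beta-diversity variation (pseudo-F 81.6) —
while the same removals explain only 10.7 % of function-level variation
(pseudo-F 5.8): with 90 % functional redundancy, functional structure is
largely decoupled from taxonomic structure. The report bundle written to
`demo/` includes the loss series (`loss_report.tsv`), ordinations, the
per-category response panel, per-level network indexes and a manifest with
config hash and file checksums; two runs with the same config and seed are
byte-identical.

The same analyses are scriptable from the shell:

```bash
funcstab simulate --out profile.tsv --seed 1
funcstab lossrun --profile profile.tsv --sizes 8,5,2,1 --out-dir loss/
funcstab run --config run.yaml
```

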