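# nemacore

Longitudinal core-microbiome and ecological-drift analysis for multi-niche
bacterial communities, built around the habitats of root-knot-nematode
(*Meloidogyne incognita*) infected plants: rhizosphere soil, infected root,
root gall, and the cuticle of second-stage juveniles (J2), each sampled over
a growing season.

## The question and the statistic

When a niche filters colonists weakly, ecologically equivalent strains drift:
a genus is found in every sample of the niche, but *which* strain (ASV)
represents it differs from sample to sample. nemacore quantifies this with
the **ASV/taxon ratio**

```
R = |core ASVs| / |core taxa|
```

computed per (niche, time point) group, where the 100% core microbiome is
the set of ASVs (or taxa, after collapsing ASVs to their lowest available
taxonomic level) present in *every* sample of the group. `R << 1` means
strong drift (core genera lack core ASVs); `R >= 1` means a selective,
deterministic niche that keeps the same strains everywhere. The same ratio
is computed on the *unique* core (core members of no other niche at that
time point), and niches are compared with Mann-Whitney U tests on their R
distributions over time points, Benjamini-Hochberg corrected (q-values).

A second, phylogenetic signature of selection: for each niche's core ASVs
that share a taxon ("congeneric" ASVs), the pairwise patristic distance on
the community phylogeny should be short in a selective niche (the niche
keeps a narrow subclade) and long in a drifting one.

Around these sit the standard stack, implemented from their definitions:
alpha diversity (observed ASVs, Shannon in bits, Pielou's evenness, Faith's
PD with the rooted convention), unweighted and weighted UniFrac, PCoA with
biplot loadings, Kruskal-Wallis / Mann-Whitney / Wilcoxon / PERMANOVA, and a
longitudinal feature-volatility analysis (importance = Euclidean norm of the
temporal mean-relative-abundance vector; net average change = mean
consecutive difference) with the curated succession-heatmap layers.

A seeded synthetic-community generator emulates the study design (four
niches of differing selectivity, six time points, genus-structured phylogeny
with strain pools, succession, multinomial sequencing depth), so the entire
pipeline is testable without any sequence download. See
`docs/methods.md` for the generative model and its assumptions.

## Worked example

```python
from nemacore import GeneratorConfig, simulate_dataset, drift_analysis

cfg = GeneratorConfig(seed=1)          # default four-niche, six-time-point study
table, taxonomy, metadata, tree = simulate_dataset(cfg)
res = drift_analysis(table, metadata, taxonomy, time_points=(2, 3, 4, 6))
print(res.r_table.groupby("niche")["R_core"].median())
```

prints (seed 1):

```
niche
J2                  2.227273
gall                0.801948
rhizosphere_soil    1.038462
root                1.216667
Name: R_core, dtype: float64
```

The J2 cuticle — the most selective habitat — carries about twice as many
core ASVs as core taxa (every core genus is represented by the *same*
strains in all samples, often several of them), while the rhizosphere and
gall hover near or below 1: their core genera are frequently represented by
different strains in different samples, the signature of ecological drift.
The congeneric patristic distances tell the same story from the tree: with
the same seed, the median distance between congeneric core ASVs is 0.20 in
J2 against 1.05 in rhizosphere soil.

The command-line interface mirrors the library:

```
nemacore simulate --out data/ --seed 1
nemacore drift --table data/feature_table.tsv --taxonomy data/taxonomy.tsv \
    --metadata data/metadata.tsv --min-depth 8828 --out drift/
nemacore run-all --out run/ --seed 1        # every stage, manifest + checksums
```

`run-all` executes depth filtering (samples with fewer than 8,828 reads are
excluded), alpha/beta diversity with per-time-point gall-vs-root tests, the
drift analysis raw and with sample-size-normalized groups, the congeneric
distance comparison, and per-niche feature volatility. Identical config and
seed give byte-identical outputs.

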