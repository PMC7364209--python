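# Methods

## Scope and data model

The pipeline starts from an ASV count table (samples x features,
non-negative integers), a taxonomy map (feature -> ranked lineage), sample
metadata (niche in {rhizosphere_soil, root, gall, J2}, time point, plant),
and a rooted phylogeny with branch lengths whose leaves cover the ASVs.
Read-level processing (primer trimming, denoising, chimera removal,
classification, tree inference) is upstream and out of scope; trees are
inputs, with a neighbor-joining builder available for self-contained
analyses on distance matrices.

Samples with fewer than 8,828 reads are excluded before analysis; the
boundary is inclusive (a sample with exactly 8,828 reads is kept, matching a
retention rule phrased as "fewer than"). All-zero features are retained
after sample exclusion unless pruning is requested, since core/prevalence
statistics are unaffected by empty columns and keeping them preserves
feature-set alignment across stages.

The "lowest available taxonomic level" of a feature is the last non-empty,
non-placeholder rank of its lineage; by default any non-empty token counts,
and placeholder tokens (e.g. "uncultured") can be declared. Collapsing sums
ASV counts within this label and conserves per-sample totals exactly
(integer arithmetic).

## Core microbiomes and the drift ratio R

For one (niche, time point) group of n samples, a feature is core at
threshold t when present (count > 0) in at least ceil(t*n) samples; the
default t = 1.0 demands presence in all samples. Presence has no minimum
count floor. The drift ratio is R = |core ASVs| / |core taxa|; when the
taxon core is empty R is undefined and flagged (NaN), never an exception.
The unique core of a niche is the subset of its core that belongs to no
other niche's core at that time point — "core only here", not "absent from
every sample elsewhere"; the stricter sample-level reading is available via
a flag.

Niche comparisons pool R over the analysis time points ({2, 3, 4, 6} by
default: J2 samples are missing at time point 1 and sparse at 5) and test
all niche pairs with two-sided Mann-Whitney U, BH-corrected within each of
three pooling families: core-only, unique-only, and pooled (core + unique
concatenated). All three are reported because the pooling the original
analysis used is not knowable from its description.

Sample-size normalization (the `normalize` flag) balances every niche to the
smallest niche's sample count within each time point by seeded uniform
subsampling without replacement, removing the prevalence advantage of small
groups (a 100% core is easier to enter with 6 samples than with 50).

## Congeneric patristic distances

Within a niche's ASV-level core, ASVs sharing their lowest taxonomic level
form congeneric groups (singletons dropped); all within-group pairwise
patristic distances, pooled over taxa and analysis time points, form the
niche's distance distribution. Pairs recurring at several time points count
once per time point, mirroring per-subset distributions that are then
pooled. Distances are read off the supplied global tree; per-genus trees are
not re-inferred (reference-augmented ML inference is out of scope), and the
statistic itself is agnostic to how the tree was built. Distributions are
compared pairwise by Mann-Whitney U with BH correction, reporting medians.

## Diversity stack

* Shannon entropy uses log2 (bits); Pielou's evenness H / log2(observed) is
  undefined (NaN) below two observed features.
* Faith's PD uses the rooted convention: the minimal subtree connecting the
  observed leaves always includes the root, so a single-feature sample
  scores its root-to-leaf path length.
* UniFrac is computed from a per-branch decomposition (branch length x
  per-sample presence or read-mass fraction below the branch). Unweighted:
  unique branch length over union branch length. Weighted: sum of
  l_b * |p_A(b) - p_B(b)|, unnormalized by default; the normalized variant
  divides by sum l_b (p_A(b) + p_B(b)) and lies in [0, 1].
* PCoA eigendecomposes the double-centered -D^2/2 matrix; negative
  eigenvalues are dropped with their magnitudes retained for diagnostics,
  and proportion explained is relative to the positive-eigenvalue sum.
  Biplot loadings place each feature at the relative-abundance-weighted mean
  of sample coordinates, ranked by norm.

## Testing layer

Mann-Whitney U uses exact enumeration when both groups have n <= 8 without
ties, otherwise the tie-corrected normal approximation with continuity
correction. Wilcoxon signed-rank drops zero differences (reducing n), exact
null for n <= 15 without ties. Kruskal-Wallis applies the tie correction
with a chi-square null; all-identical input returns H = 0, p = 1.
PERMANOVA computes Anderson's pseudo-F directly from the squared distance
matrix and permutes group labels with a seeded generator; p-values use the
(1 + hits) / (1 + permutations) convention and can never be zero. Note that
with tie-inclusive counting the minimal attainable p is bounded below by the
fraction of label permutations reproducing the observed partition, not by
1/(permutations + 1). Benjamini-Hochberg adjusted p-values are reported as
q-values; each analysis corrects its own family.

The gall-vs-root beta-diversity contrast is reported two ways per time
point, because the pairing construction of the original description is
underspecified: a PERMANOVA on the niche labels of the root and gall
samples, and a one-sample Wilcoxon of within-plant root-gall distances
against the median within-niche distance of the same time point.

## Feature volatility and the succession heatmap

Per niche, a feature's temporal profile is the mean of per-sample relative
abundances at each time point (not the pooled-count ratio, which unequal
depths would bias). Importance is the Euclidean norm of this profile; net
average change is its mean consecutive difference, (last - first)/(T - 1).
Features with all-zero profiles in the niche are excluded before any top-k
selection. The curated cohort is, in order: top-15 ASVs and top-15 taxa by
importance; top-5 increasing and top-5 decreasing ASVs, then taxa, by net
change; each included taxon's two most abundant ASVs; and, for closure,
every included ASV's taxon. Ties break by importance (descending) then
identifier, making the cohort invariant to input order. The heatmap bundle
holds three aligned layers — mean relative abundance, each ASV's share of
its taxon's reads (RAn; defined as 0 and flagged where the taxon has no
reads), and the peak-normalized temporal profile — with taxa sorted by
peaking time point and their ASVs nested beneath. On taxon rows the RA
layer shows the taxon's own profile; on ASV rows, the ASV's.

## The synthetic community generator

The generator emulates the study design, not its sequences. Defaults: 24
genera x 8 strains (192 ASVs), four niches with selectivities 0.15 (soil),
0.50 (root), 0.60 (gall), 0.90 (J2), six time points, 8 samples per group,
10,000 reads per sample (above the 8,828 retention threshold), J2 absent at
time point 1. Sample sizes and richness are desk-scale stand-ins for a
study two orders of magnitude larger; they were chosen so that every
downstream statistic is exercised in seconds.

Mechanisms, each a deliberate model choice:

* **Phylogeny.** A star of genus clades on long (unit) stems; each genus
  splits into two subclades with stems of 8x the within-genus branch scale
  (exponential, mean `within_genus_depth` = 0.05), so within- and
  cross-subclade patristic distances separate cleanly and both shrink to 0
  as `within_genus_depth` does.
* **Succession.** Genus g follows a Gaussian bump floor +
  exp(-(t - peak_g)^2 / 2w^2) (peaks evenly spread, width 1.5),
  renormalized across genera per time point. Because abundances are
  compositional, a genus's *share* peaks where its normalized profile does,
  which at the season edges can differ from its absolute peak.
* **Habitat filtering.** Each (niche, genus) carries a fixed multiplier:
  lognormal (sd 0.75) times a residency draw (resident with probability
  0.4; non-residents are scaled by 1e-3, and a genus excluded everywhere is
  reinstated in one niche). Without residency, every niche shares the same
  core genera and the unique-core ratio is undefined everywhere.
* **Strain pools and drift.** Within a genus, per-sample strain weights are
  Dirichlet. The baseline concentrations are fixed per seed: total mass
  epsilon*K per genus, split evenly between the two subclades and spread
  within each by a Dirichlet(commonness = 0.3) draw — every subclade has a
  dominant cosmopolitan strain plus transient ones, the heavy-tailed
  abundance structure that lets some strains be core even under drift (and
  makes a drifting niche's congeneric core pairs predominantly
  cross-subclade, hence long). epsilon = 0.15: sparse enough that strain
  dropout actually occurs at realistic genus read depths; with much larger
  epsilon every strain of every abundant genus is deeply sampled and the
  drift signal vanishes.
* **Selectivity.** With probability s (the niche's selectivity), a sample's
  genus draw adds mass s^2 * M / m (M = 20) on the m strains of the niche's
  preferred subclade. At s = 1 the preferred subclade dominates every
  sample (R > 1, short congeneric distances — the J2 phenotype); at s = 0
  the symmetric baseline alone applies and dominant-strain identity drifts
  freely. The quadratic ramp matters: a linear one suppresses the
  cosmopolitan strains at weak selection faster than it installs preferred
  ones, making mean R dip before it rises.
* **Counts.** Multinomial at fixed depth per sample. All randomness flows
  from one seed through named independent streams (tree, niche preferences,
  counts, commonness, affinities), so a seed fixes the dataset bytewise.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: sequencing error and chimeras, compositional
depth variation across samples, within-plant covariance beyond shared plant
labels, taxonomic misassignment, and any uncertainty in the input tree.
Parameter-recovery results show the statistics recover *this* model's
selectivity ordering, not that real niches behave like the model.

## Numerical and degenerate-input conventions

Distance matrices are symmetrized against float noise and clamped at 0;
unweighted UniFrac of two empty-overlap communities is 1 by construction,
and 0/0 branch unions yield distance 0. R with an empty taxon core, Pielou
with one observed feature, and temporal heatmap rows with all-zero profiles
are flagged rather than raised. Subsampling, permutation tests and the
generator require explicit seeds in pipeline contexts; `run_all` derives
all stage seeds from the single run seed and writes a manifest with SHA-256
checksums, so identical config + seed reproduce byte-identical outputs.

## Known limitations

* Per-genus ML tree inference with external references is out of scope;
  congeneric distances inherit whatever tree is supplied.
* The 100% prevalence criterion is sharp: with very few samples per group a
  core is easy to enter, which is why the normalized (balanced) variant is
  always computed alongside the raw one.
* The Wilcoxon pairing for the root-gall beta contrast is one defensible
  construction among several; both it and the PERMANOVA view are emitted so
  downstream users can choose.
* p-values from 999 permutations resolve no finer than 1e-3; raise
  `n_permutations` where finer resolution matters.
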