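"""Synthetic longitudinal multi-niche community generator.

Emulates the sampling design of a root-knot-nematode infection time course:
four habitats (rhizosphere soil, infected root, gall, J2 cuticle) sampled over
six time points, with genus-level succession, niche-dependent ecological
drift, and a genus-structured phylogeny.

Model
-----
Each genus ``g`` has a Gaussian succession bump over time,
``A_g(t) = floor + exp(-(t - peak_g)^2 / (2 width_g^2))``, multiplied by a
fixed log-normal habitat affinity per (niche, genus) and renormalized across
genera per time point — different niches therefore filter the genus pool
differently.  Within a genus, per-sample strain (ASV) weights are
Dirichlet-distributed; how concentrated they are encodes the niche's
selectivity ``s``:

* every strain carries a fixed baseline concentration (drawn once per genus
  from a Dirichlet "commonness" prior and shared by all niches), so each
  genus has a few cosmopolitan strains and a tail of transient ones;
* with probability ``s`` an extra mass ``s^2 * M / m`` is added on the ``m``
  strains of the niche's preferred subclade of that genus, so selective
  niches repeatedly favour the same phylogenetically narrow strain pool
  (the quadratic ramp keeps weak selection from merely suppressing the
  cosmopolitan strains without installing its own);
* otherwise the sparse baseline Dirichlet alone applies, and the dominant
  strain identity varies freely from sample to sample (ecological drift).

At ``s = 1`` every sample's genus reads are dominated by the fixed preferred
subclade; at ``s = 0`` strain identities are exchangeable.  Read counts per
sample are multinomial at a fixed sequencing depth.

All randomness flows from one integer seed through named, independent
streams; the same seed always produces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .data_model import FeatureTable, SampleMetadata, TaxonomyMap, validate_tree

_DEFAULT_NICHES = (
    ("rhizosphere_soil", 0.15),
    ("root", 0.50),
    ("gall", 0.60),
    ("J2", 0.90),
)

_PHYLA = ("p__Pseudomonadota", "p__Actinomycetota", "p__Bacillota", "p__Bacteroidota")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic community.

    Defaults reflect the study design being emulated: four niches of
    increasing selectivity (soil < root < gall < J2), six time points spanning
    a growing season, sequencing depth above the 8,828-read retention
    threshold, and J2 samples absent from the first time point (juveniles are
    only collected from time point 2 onward).
    """

    n_genera: int = 24
    strains_per_genus: int = 8
    niches: tuple = _DEFAULT_NICHES
    n_time_points: int = 6
    samples_per_group: int = 8
    depth: int = 10_000
    #: per-genus (peak_time, width); None = peaks evenly spread over the season
    succession: tuple | None = None
    #: scale of exponential branch lengths separating congeneric strains
    within_genus_depth: float = 0.05
    #: baseline Dirichlet concentration per strain (mean over the genus)
    epsilon: float = 0.15
    #: extra Dirichlet mass granted to the preferred subclade (scaled by s)
    mass: float = 20.0
    #: concentration of the fixed per-strain commonness weights; smaller
    #: values make a genus's baseline abundances more uneven, so a few
    #: cosmopolitan strains stay core even under strong drift
    commonness: float = 0.3
    #: abundance floor of the succession bump (keeps genera detectable off-peak)
    succession_floor: float = 0.05
    #: sd of the log-normal per-(niche, genus) habitat-affinity multiplier;
    #: niches filter genera differently, so each niche has some genera of its
    #: own among its core taxa (0 disables habitat filtering)
    niche_affinity_sigma: float = 0.75
    #: probability a genus is a resident of a given niche; non-residents get
    #: a ~1e-3 affinity so each niche draws on a partly private genus pool
    niche_membership: float = 0.4
    #: (niche, time_point) groups that yield no samples
    missing_groups: tuple = (("J2", 1),)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genera < 1 or self.strains_per_genus < 1:
            raise ValueError("n_genera and strains_per_genus must be >= 1")
        if self.n_time_points < 1 or self.samples_per_group < 1:
            raise ValueError("n_time_points and samples_per_group must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for name, s in self.niches:
            if not 0.0 <= float(s) <= 1.0:
                raise ValueError(f"selectivity of niche {name!r} must be in [0, 1]")
        if self.epsilon <= 0 or self.mass < 0 or self.commonness <= 0:
            raise ValueError("epsilon and commonness must be > 0, mass >= 0")
        if self.succession is not None and len(self.succession) != self.n_genera:
            raise ValueError("succession must list one (peak, width) per genus")

    # -- derived quantities -------------------------------------------------

    def genus_names(self) -> list[str]:
        return [f"g__Genus{g + 1:02d}" for g in range(self.n_genera)]

    def feature_ids(self) -> list[str]:
        return [f"asv-{g + 1:02d}-{j + 1:02d}"
                for g in range(self.n_genera)
                for j in range(self.strains_per_genus)]

    def succession_params(self) -> list[tuple[float, float]]:
        if self.succession is not None:
            return [(float(p), float(w)) for p, w in self.succession]
        T, G = self.n_time_points, self.n_genera
        if G == 1:
            return [((1 + T) / 2.0, 1.5)]
        peaks = 1.0 + (T - 1) * np.arange(G) / (G - 1)
        return [(float(p), 1.5) for p in peaks]

    def succession_profile(self) -> np.ndarray:
        """Expected genus relative abundances, shape (n_genera, n_time_points)."""
        t = np.arange(1, self.n_time_points + 1, dtype=float)
        rows = []
        for peak, width in self.succession_params():
            rows.append(self.succession_floor +
                        np.exp(-((t - peak) ** 2) / (2.0 * width ** 2)))
        A = np.asarray(rows)
        return A / A.sum(axis=0, keepdims=True)


def _stream(seed: int, key: int) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def _random_subtree(tips: list[str], rng: np.random.Generator,
                    scale: float) -> TreeNode:
    """Random coalescent-style binary subtree with exponential branch lengths."""
    nodes = [TreeNode(name=t, length=float(rng.exponential(scale)) if scale > 0 else 0.0)
             for t in tips]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(
            length=float(rng.exponential(scale)) if scale > 0 else 0.0,
            children=[left, right])
        nodes.append(parent)
    return nodes[0]


def genus_subclades(config: GeneratorConfig, genus_index: int) -> tuple[list[int], list[int]]:
    """Strain indices of the genus's two subclades (second empty if k < 2)."""
    k = config.strains_per_genus
    half = (k + 1) // 2
    return list(range(half)), list(range(half, k))


def simulate_phylogeny(config: GeneratorConfig) -> TreeNode:
    """Rooted tree of ``n_genera`` monophyletic clades of strains.

    Each genus clade splits into two subclades whose internal branch lengths
    are exponential with mean ``within_genus_depth``; genus stems are long
    (unit length) so between-genus distances dwarf within-genus ones.  The
    topology and lengths are reproducible from the config seed.
    """
    config.validate()
    rng = _stream(config.seed, 0)
    scale = config.within_genus_depth
    clades = []
    for g in range(config.n_genera):
        ids = [f"asv-{g + 1:02d}-{j + 1:02d}" for j in range(config.strains_per_genus)]
        left_idx, right_idx = genus_subclades(config, g)
        if not right_idx:  # single subclade (k == 1)
            clade = _random_subtree([ids[i] for i in left_idx], rng, scale)
        else:
            left = _random_subtree([ids[i] for i in left_idx], rng, scale)
            right = _random_subtree([ids[i] for i in right_idx], rng, scale)
            # subclade stems scale with within-genus depth so the
            # within-subclade vs cross-subclade contrast is controlled
            left.length += 8.0 * scale
            right.length += 8.0 * scale
            clade = TreeNode(children=[left, right])
        clade.length = 1.0
        clade.name = f"genus{g + 1:02d}"
        clades.append(clade)
    root = TreeNode(children=clades, length=0.0, name="root")
    return validate_tree(root)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def simulate_taxonomy(config: GeneratorConfig) -> TaxonomyMap:
    """Six-rank lineages; the genus rank is the lowest available level."""
    lineages = {}
    for g in range(config.n_genera):
        phylum = _PHYLA[g % len(_PHYLA)]
        genus = f"g__Genus{g + 1:02d}"
        lineage = ("d__Bacteria", phylum, f"c__Class{g % 3 + 1}",
                   f"o__Order{g % 5 + 1}", f"f__Family{g + 1:02d}", genus, "")
        for j in range(config.strains_per_genus):
            lineages[f"asv-{g + 1:02d}-{j + 1:02d}"] = lineage
    return TaxonomyMap(lineages)


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------

def preferred_subclades(config: GeneratorConfig) -> dict[str, list[list[int]]]:
    """Per niche, the preferred subclade (list of strain indices) per genus."""
    rng = _stream(config.seed, 1)
    prefs: dict[str, list[list[int]]] = {}
    for name, _s in config.niches:
        per_genus = []
        for g in range(config.n_genera):
            left, right = genus_subclades(config, g)
            options = [left, right] if right else [left]
            per_genus.append(options[int(rng.integers(len(options)))])
        prefs[name] = per_genus
    return prefs


def niche_affinities(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Fixed per-genus abundance multipliers for each niche.

    Habitat filtering has two components: a continuous log-normal affinity
    (sd ``niche_affinity_sigma``) and a residency draw — with probability
    ``1 - niche_membership`` a genus is effectively excluded from a niche
    (multiplier scaled by 1e-3).  A genus excluded everywhere is reinstated
    in one niche so no taxon disappears from the study entirely.
    """
    rng = _stream(config.seed, 4)
    G = config.n_genera
    names = [name for name, _s in config.niches]
    out: dict[str, np.ndarray] = {}
    for name in names:
        if config.niche_affinity_sigma > 0:
            aff = rng.lognormal(0.0, config.niche_affinity_sigma, size=G)
        else:
            aff = np.ones(G)
        out[name] = aff
    if config.niche_membership < 1.0 and len(names) > 0:
        resident = rng.random((len(names), G)) < config.niche_membership
        orphan = ~resident.any(axis=0)
        if orphan.any():  # give orphans a home niche
            homes = rng.integers(len(names), size=int(orphan.sum()))
            resident[homes, np.flatnonzero(orphan)] = True
        for i, name in enumerate(names):
            out[name] = out[name] * np.where(resident[i], 1.0, 1e-3)
    return out


def expected_genus_profile(config: GeneratorConfig, niche: str) -> np.ndarray:
    """Expected genus relative abundances in one niche, shape (G, T):
    the succession profile re-weighted by the niche's habitat affinities."""
    aff = niche_affinities(config)[niche]
    A = config.succession_profile() * aff[:, None]
    return A / A.sum(axis=0, keepdims=True)


def baseline_concentrations(config: GeneratorConfig) -> np.ndarray:
    """Fixed per-strain Dirichlet base concentrations, shape (G, K).

    Each genus's strains share total mass ``epsilon * K``.  The mass is split
    evenly between the genus's two subclades and then spread within each
    subclade by a fixed Dirichlet(commonness) draw — abundance structure is
    clade-conserved, so every subclade carries its own dominant cosmopolitan
    strain plus a tail of transient ones.  The draw is part of the
    community's identity: it is made once per seed and shared by all niches
    and samples.
    """
    rng = _stream(config.seed, 3)
    G, K = config.n_genera, config.strains_per_genus
    base = np.empty((G, K))
    for g in range(G):
        total = config.epsilon * K
        parts = [p for p in genus_subclades(config, g) if p]
        for part in parts:
            w = rng.dirichlet(np.full(len(part), config.commonness))
            base[g, part] = (total / len(parts)) * np.maximum(w, 1e-6)
    return base


def simulate_dataset(config: GeneratorConfig):
    """Simulate the full dataset.

    Returns ``(FeatureTable, TaxonomyMap, SampleMetadata, TreeNode)``.  Sample
    identifiers encode niche, time point and plant; the same plant index
    recurs across niches and time points, so within-plant cross-niche
    comparisons are possible.
    """
    config.validate()
    tree = simulate_phylogeny(config)
    taxonomy = simulate_taxonomy(config)
    prefs = preferred_subclades(config)
    base = baseline_concentrations(config)
    affinities = niche_affinities(config)
    rng = _stream(config.seed, 2)

    G, K = config.n_genera, config.strains_per_genus
    F = G * K
    missing = {(n, int(t)) for n, t in config.missing_groups}

    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    for niche, s in config.niches:
        s = float(s)
        profile = expected_genus_profile(config, niche)  # (G, T)
        for t in range(1, config.n_time_points + 1):
            if (niche, t) in missing:
                continue
            n_s = config.samples_per_group
            weights = np.zeros((n_s, F))
            for g in range(G):
                alpha = np.tile(base[g], (n_s, 1))
                if s > 0 and config.mass > 0:
                    boosted = rng.random(n_s) < s
                    members = prefs[niche][g]
                    alpha[np.ix_(boosted, members)] += s * s * config.mass / len(members)
                gammas = rng.gamma(alpha)
                gammas /= gammas.sum(axis=1, keepdims=True)
                weights[:, g * K:(g + 1) * K] = profile[g, t - 1] * gammas
            weights /= weights.sum(axis=1, keepdims=True)
            counts = rng.multinomial(config.depth, weights)
            for p in range(n_s):
                sid = f"{niche}.t{t}.p{p + 1:02d}"
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "niche": niche,
                                  "time_point": t, "plant_id": f"plant{p + 1:02d}"})
            rows.append(counts)

    counts = np.vstack(rows)
    table = FeatureTable(pd.DataFrame(counts, index=sample_ids,
                                      columns=config.feature_ids()))
    metadata = SampleMetadata(
        pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, taxonomy, metadata, tree


def write_dataset(config: GeneratorConfig, outdir: str | Path):
    """Simulate and write the four standard files plus a provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, taxonomy, metadata, tree = simulate_dataset(config)
    table.to_tsv(outdir / "feature_table.tsv")
    taxonomy.to_tsv(outdir / "taxonomy.tsv")
    metadata.to_tsv(outdir / "metadata.tsv")
    tree.write(str(outdir / "tree.nwk"), format="newick")
    sidecar = {"generator": "nemacore.synthetic.simulate_dataset",
               "config": asdict(config)}
    with open(outdir / "generator_config.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return table, taxonomy, metadata, tree
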