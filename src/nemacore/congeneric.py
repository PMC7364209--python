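"""Patristic distances between congeneric core ASVs.

A very selective niche should sustain congeneric ASVs (ASVs sharing their
lowest available taxonomic level, typically a genus) that are phylogenetically
closer to one another than congeneric ASVs in a stochastic niche.  This module
groups a niche's core ASVs by taxon, reads their pairwise patristic (path
length) distances off a supplied tree, pools them into one distribution per
niche and compares niches with Mann-Whitney U tests.

A neighbor-joining builder is included so self-contained analyses can derive a
tree from an ASV distance matrix when no inferred phylogeny is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .data_model import (FeatureTable, GroupKey, SampleMetadata, TaxonomyMap,
                         ValidationError)
from .core_drift import CoreSet, core_features
from .stats import bh_adjust, mann_whitney_u

logger = logging.getLogger(__name__)


def congeneric_groups(core: CoreSet, taxonomy: TaxonomyMap) -> dict[str, list[str]]:
    """Group a core set's ASVs by shared lowest taxonomic level.

    Only groups of two or more ASVs are returned (singletons yield no pairs);
    dropped singletons are logged.
    """
    if core.level != "asv":
        raise ValidationError("congeneric grouping requires an ASV-level core")
    by_taxon: dict[str, list[str]] = {}
    for asv in core.members:
        by_taxon.setdefault(taxonomy.lowest_level(asv), []).append(asv)
    groups = {t: sorted(asvs) for t, asvs in by_taxon.items() if len(asvs) >= 2}
    singletons = len(by_taxon) - len(groups)
    if singletons:
        logger.debug("congeneric: %d singleton taxa dropped for %s",
                     singletons, core.group)
    return dict(sorted(groups.items()))


def patristic_distance(tree: TreeNode, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths along the unique path between two leaves."""
    if leaf_a == leaf_b:
        _find_tip(tree, leaf_a)
        return 0.0
    a = _find_tip(tree, leaf_a)
    b = _find_tip(tree, leaf_b)
    return float(a.distance(b))


def _find_tip(tree: TreeNode, name: str) -> TreeNode:
    try:
        node = tree.find(name)
    except Exception:
        raise ValidationError(f"leaf {name!r} not found in tree") from None
    if not node.is_tip():
        raise ValidationError(f"{name!r} is an internal node, not a leaf")
    return node


def patristic_matrix(tree: TreeNode, leaves: list[str]) -> pd.DataFrame:
    """All pairwise patristic distances among the named leaves."""
    for name in leaves:
        _find_tip(tree, name)
    dm = tree.tip_tip_distances(endpoints=list(leaves))
    df = pd.DataFrame(np.asarray(dm.data), index=list(dm.ids), columns=list(dm.ids))
    return df.loc[leaves, leaves]


def nj_tree(distances: DistanceMatrix | pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix (n >= 3).

    Additive matrices are reconstructed exactly (topology and branch
    lengths).  Negative branch-length estimates, which NJ can produce on
    noisy input, are clamped to zero.
    """
    if isinstance(distances, pd.DataFrame):
        distances = DistanceMatrix(distances.to_numpy(dtype=float),
                                   ids=list(distances.index))
    if len(distances.ids) < 3:
        raise ValueError("nj_tree requires at least 3 taxa")
    tree = nj(distances)
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
        if node.length is None:
            node.length = 0.0
    return tree


@dataclass
class CongenericDistanceSet:
    """Pooled congeneric patristic distances for one niche."""

    niche: str
    pairs: pd.DataFrame  # columns: time_point, taxon, asv_a, asv_b, distance

    @property
    def distances(self) -> np.ndarray:
        return self.pairs["distance"].to_numpy(dtype=float)

    def median(self) -> float:
        d = self.distances
        return float(np.median(d)) if d.size else float("nan")


def congeneric_analysis(table: FeatureTable, metadata: SampleMetadata,
                        taxonomy: TaxonomyMap, tree: TreeNode,
                        time_points=(2, 3, 4, 6), niches=None,
                        threshold: float = 1.0) -> dict[str, CongenericDistanceSet]:
    """Congeneric core-ASV distances per niche, pooled over time points.

    For each (niche, time point) the ASV-level 100% core is computed, its
    members grouped by taxon, and all within-taxon pairwise patristic
    distances collected.  Pairs recurring at several time points contribute
    once per time point (each subset's distribution is pooled).
    """
    wanted = list(niches) if niches is not None else metadata.niches
    tip_cache: dict[tuple, float] = {}
    out: dict[str, CongenericDistanceSet] = {}
    for niche in wanted:
        rows = []
        for tp in time_points:
            key = GroupKey(niche, int(tp))
            if not metadata.group(key):
                continue
            core = core_features(table, metadata, key, "asv", threshold=threshold)
            groups = congeneric_groups(core, taxonomy)
            needed = sorted({a for asvs in groups.values() for a in asvs})
            if not needed:
                continue
            dmat = patristic_matrix(tree, needed)
            for taxon, asvs in groups.items():
                for a, b in combinations(asvs, 2):
                    rows.append({"time_point": int(tp), "taxon": taxon,
                                 "asv_a": a, "asv_b": b,
                                 "distance": float(dmat.loc[a, b])})
        out[niche] = CongenericDistanceSet(
            niche, pd.DataFrame(rows, columns=["time_point", "taxon",
                                               "asv_a", "asv_b", "distance"]))
    return out


def compare_congeneric_distributions(dist_sets: dict[str, CongenericDistanceSet]
                                     ) -> pd.DataFrame:
    """Pairwise Mann-Whitney U on pooled per-niche distance distributions.

    Niches without any congeneric pair are excluded (logged).  Medians are
    reported alongside U, p and BH-adjusted q.
    """
    usable = {n: s for n, s in dist_sets.items() if s.distances.size > 0}
    dropped = set(dist_sets) - set(usable)
    if dropped:
        logger.info("congeneric: niches without pairs excluded: %s",
                    sorted(dropped))
    if len(usable) < 2:
        return pd.DataFrame(columns=["niche_a", "niche_b", "U", "p_value",
                                     "q_value", "n_a", "n_b",
                                     "median_a", "median_b", "method"])
    rows = []
    for a, b in combinations(sorted(usable), 2):
        res = mann_whitney_u(usable[a].distances, usable[b].distances)
        rows.append({"niche_a": a, "niche_b": b, "U": res.statistic,
                     "p_value": res.p_value,
                     "n_a": usable[a].distances.size,
                     "n_b": usable[b].distances.size,
                     "median_a": usable[a].median(),
                     "median_b": usable[b].median(),
                     "method": res.method})
    df = pd.DataFrame(rows)
    df.insert(4, "q_value", bh_adjust(df["p_value"].to_numpy()))
    return df


def pairs_table(dist_sets: dict[str, CongenericDistanceSet]) -> pd.DataFrame:
    frames = []
    for niche in sorted(dist_sets):
        df = dist_sets[niche].pairs.copy()
        df.insert(0, "niche", niche)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["niche", "time_point", "taxon",
                                     "asv_a", "asv_b", "distance"])
    return pd.concat(frames, ignore_index=True)
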