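"""Core microbiomes and the ecological-drift ratio R.

For every (niche, time point) group, the 100%-prevalence core microbiome is
computed at the ASV level and, after collapsing to the lowest available
taxonomic level, at the taxon level.  The ratio

    R = (# core ASVs) / (# core taxa)

is a relative measure of ecological drift: a core genus without a core ASV is
represented by different strains in different samples, so low R means strong
stochastic strain turnover, whereas a highly selective niche keeps the same
strains everywhere (R >= 1).  The same ratio is computed on the "unique" core
(core members found in no other niche's core at that time point), and niches
are compared by Mann-Whitney U tests on their R distributions over time
points, Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data_model import (FeatureTable, GroupKey, SampleMetadata, TaxonomyMap,
                         ValidationError, collapse_by_lowest_taxon,
                         subsample_groups)
from .stats import TestResult, bh_adjust, mann_whitney_u

logger = logging.getLogger(__name__)

#: Time points used in the drift analyses (J2 samples are unavailable at
#: time point 1 and sparse at 5, so the comparison is restricted).
DEFAULT_TIME_POINTS = (2, 3, 4, 6)


@dataclass(frozen=True)
class CoreSet:
    """Features present in (at least) a threshold fraction of a group's samples."""

    group: GroupKey
    level: str                 # "asv" | "taxon"
    members: tuple
    prevalence_threshold: float = 1.0
    n_samples: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def member_set(self) -> frozenset:
        return frozenset(self.members)


def core_features(table: FeatureTable, metadata: SampleMetadata, group: GroupKey,
                  level: str = "asv", taxonomy: TaxonomyMap | None = None,
                  threshold: float = 1.0) -> CoreSet:
    """Core features of one (niche, time point) group.

    A feature belongs to the core when it is present (count > 0) in at least
    ``ceil(threshold * n)`` of the group's ``n`` samples; at the default
    threshold 1.0 this means *all* samples.  At ``level="taxon"`` presence of
    a taxon in a sample means any of its ASVs is present.
    """
    if level not in ("asv", "taxon"):
        raise ValueError(f"unknown level {level!r}")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    samples = metadata.group(group)
    samples = [s for s in samples if s in set(table.sample_ids)]
    if not samples:
        raise ValidationError(f"group {group} has no samples")
    sub = table.subset_samples(samples)
    if level == "taxon":
        if taxonomy is None:
            raise ValueError("taxon-level core requires a TaxonomyMap")
        sub = collapse_by_lowest_taxon(sub, taxonomy)
    need = math.ceil(threshold * len(samples))
    prev = (sub.data > 0).sum(axis=0)
    members = tuple(sorted(prev.index[prev >= need]))
    return CoreSet(group, level, members, threshold, len(samples))


def unique_core(cores: dict[str, CoreSet], focal_niche: str,
                strict: bool = False,
                table: FeatureTable | None = None,
                metadata: SampleMetadata | None = None,
                taxonomy: TaxonomyMap | None = None) -> CoreSet:
    """The focal niche's core members found in no other niche's core.

    ``cores`` maps niche name -> CoreSet, all at the same time point and
    level.  With ``strict`` the requirement hardens to absence from every
    *sample* of the other niches at that time point (needs the table).
    """
    focal = cores[focal_niche]
    levels = {c.level for c in cores.values()}
    tps = {c.group.time_point for c in cores.values()}
    if len(levels) != 1 or len(tps) != 1:
        raise ValidationError("unique_core requires cores at one level and time point")
    others = [c for niche, c in cores.items() if niche != focal_niche]
    if strict:
        if table is None or metadata is None:
            raise ValueError("strict unique_core requires table and metadata")
        present_elsewhere: set = set()
        for other in others:
            samples = metadata.group(other.group)
            samples = [s for s in samples if s in set(table.sample_ids)]
            if not samples:
                continue
            sub = table.subset_samples(samples)
            if focal.level == "taxon":
                sub = collapse_by_lowest_taxon(sub, taxonomy)
            prev = (sub.data > 0).any(axis=0)
            present_elsewhere |= set(prev.index[prev])
        members = tuple(m for m in focal.members if m not in present_elsewhere)
    else:
        other_members: set = set()
        for other in others:
            other_members |= other.member_set()
        members = tuple(m for m in focal.members if m not in other_members)
    return CoreSet(focal.group, focal.level, members, focal.prevalence_threshold,
                   focal.n_samples)


def r_ratio(asv_core: CoreSet, taxon_core: CoreSet) -> float:
    """Core-ASV count over core-taxon count; NaN when the taxon core is empty."""
    if asv_core.group != taxon_core.group:
        raise ValidationError(
            f"group mismatch: {asv_core.group} vs {taxon_core.group}")
    if {asv_core.level, taxon_core.level} != {"asv", "taxon"}:
        raise ValidationError("r_ratio needs one ASV-level and one taxon-level core")
    if len(taxon_core) == 0:
        return float("nan")
    return len(asv_core) / len(taxon_core)


@dataclass
class DriftResult:
    """Per-group R values and pairwise niche comparisons.

    ``r_table`` has one row per (niche, time point) with core/unique counts
    and ratios; ``comparisons`` holds Mann-Whitney tests between niches on
    three poolings of R values over time points: ``core``, ``unique`` and
    ``pooled`` (core and unique values concatenated), each q-corrected as its
    own family.  ``core_sets`` retains the underlying memberships.
    """

    r_table: pd.DataFrame
    comparisons: pd.DataFrame
    core_sets: list = field(default_factory=list)  # (kind, CoreSet) pairs
    normalized: bool = False

    def median_r(self, niche: str, kind: str = "core") -> float:
        col = {"core": "R_core", "unique": "R_unique"}[kind]
        vals = self.r_table.loc[self.r_table["niche"] == niche, col].dropna()
        return float(vals.median()) if len(vals) else float("nan")


def drift_analysis(table: FeatureTable, metadata: SampleMetadata,
                   taxonomy: TaxonomyMap,
                   time_points=DEFAULT_TIME_POINTS,
                   niches=None,
                   normalize: bool = False,
                   threshold: float = 1.0,
                   seed: int | None = None) -> DriftResult:
    """Full drift analysis over the requested niches and time points.

    With ``normalize`` the per-time-point sample counts are first balanced
    across niches (seeded subsampling to the smallest niche), removing the
    prevalence advantage of small groups.  Groups without samples are skipped
    and logged.
    """
    if normalize:
        if seed is None:
            raise ValueError("normalize=True requires a seed")
        table, metadata = subsample_groups(table, metadata, seed=seed,
                                           time_points=time_points,
                                           niches=niches)
    wanted = list(niches) if niches is not None else metadata.niches
    rows = []
    all_sets: list[CoreSet] = []
    for tp in time_points:
        cores_asv: dict[str, CoreSet] = {}
        cores_tax: dict[str, CoreSet] = {}
        for niche in wanted:
            key = GroupKey(niche, int(tp))
            if not metadata.group(key):
                logger.info("drift: skipping empty group %s", key)
                continue
            cores_asv[niche] = core_features(table, metadata, key, "asv",
                                             threshold=threshold)
            cores_tax[niche] = core_features(table, metadata, key, "taxon",
                                             taxonomy, threshold=threshold)
        for niche in cores_asv:
            ua = unique_core(cores_asv, niche)
            ut = unique_core(cores_tax, niche)
            rows.append({
                "niche": niche, "time_point": int(tp),
                "n_samples": cores_asv[niche].n_samples,
                "core_asv_count": len(cores_asv[niche]),
                "core_taxon_count": len(cores_tax[niche]),
                "unique_asv_count": len(ua),
                "unique_taxon_count": len(ut),
                "R_core": r_ratio(cores_asv[niche], cores_tax[niche]),
                "R_unique": r_ratio(ua, ut),
            })
            all_sets += [("core", cores_asv[niche]), ("core", cores_tax[niche]),
                         ("unique", ua), ("unique", ut)]
    r_table = pd.DataFrame(rows)
    comparisons = _pairwise_r_tests(r_table, wanted)
    return DriftResult(r_table, comparisons, all_sets, normalized=normalize)


def _pairwise_r_tests(r_table: pd.DataFrame, niches) -> pd.DataFrame:
    """Mann-Whitney U between niches on R distributions, per pooling family."""
    present = [n for n in niches if len(r_table) and n in set(r_table["niche"])]
    rows = []
    for pooling in ("core", "unique", "pooled"):
        fam = []
        for a, b in combinations(present, 2):
            xa = _r_values(r_table, a, pooling)
            xb = _r_values(r_table, b, pooling)
            if len(xa) == 0 or len(xb) == 0:
                continue
            res = mann_whitney_u(xa, xb)
            fam.append({"pooling": pooling, "niche_a": a, "niche_b": b,
                        "U": res.statistic, "p_value": res.p_value,
                        "n_a": len(xa), "n_b": len(xb),
                        "median_a": float(np.median(xa)),
                        "median_b": float(np.median(xb)),
                        "method": res.method})
        if fam:
            q = bh_adjust([r["p_value"] for r in fam])
            for r, qv in zip(fam, q):
                r["q_value"] = float(qv)
            rows.extend(fam)
    df = pd.DataFrame(rows)
    if len(df):
        cols = ["pooling", "niche_a", "niche_b", "U", "p_value", "q_value",
                "n_a", "n_b", "median_a", "median_b", "method"]
        df = df[cols]
    return df


def _r_values(r_table: pd.DataFrame, niche: str, pooling: str) -> np.ndarray:
    sub = r_table[r_table["niche"] == niche]
    if pooling == "core":
        vals = sub["R_core"]
    elif pooling == "unique":
        vals = sub["R_unique"]
    else:
        vals = pd.concat([sub["R_core"], sub["R_unique"]])
    return vals.dropna().to_numpy(dtype=float)


def core_sets_table(core_sets: list) -> pd.DataFrame:
    """Flatten (kind, CoreSet) memberships into a writable table."""
    rows = []
    for kind, cs in core_sets:
        for m in cs.members:
            rows.append({"niche": cs.group.niche, "time_point": cs.group.time_point,
                         "kind": kind, "level": cs.level, "member": m,
                         "threshold": cs.prevalence_threshold,
                         "n_samples": cs.n_samples})
    return pd.DataFrame(rows, columns=["niche", "time_point", "kind", "level",
                                       "member", "threshold", "n_samples"])
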