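"""Longitudinal feature volatility and the succession heatmap.

Within one niche, every feature (ASV or collapsed taxon) is summarized by its
mean relative abundance per time point.  Two scalar statistics drive feature
curation:

* ``importance`` — the Euclidean norm of the temporal mean-relative-abundance
  vector (its distance from the null vector);
* ``net average change`` — the mean consecutive difference of the vector,
  i.e. ``(last - first) / (T - 1)``; the sign gives the trend direction.

The curated cohort combines the most important ASVs and taxa, the strongest
increasing/decreasing trends, each included taxon's two most abundant ASVs
and, for closure, every included ASV's parent taxon.  The heatmap bundle lays
these out as three aligned matrices (taxon relative abundance; each ASV's
share of its taxon's reads, "RAn"; peak-normalized temporal profiles), with
taxa sorted by peaking time point and their ASVs nested beneath them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (FeatureTable, SampleMetadata, TaxonomyMap,
                         ValidationError, collapse_by_lowest_taxon,
                         relative_abundance)

logger = logging.getLogger(__name__)

QUOTA_IMPORTANCE = 15   # most important ASVs, and taxa, per niche
QUOTA_TREND = 5         # top increasing and top decreasing, each level
QUOTA_TAXON_ASVS = 2    # most abundant ASVs pulled in per included taxon


def importance(mean_ra) -> float:
    """Euclidean distance of the temporal abundance vector from the null vector."""
    v = np.asarray(mean_ra, dtype=float)
    if ((v < 0) | (v > 1)).any():
        raise ValueError("mean relative abundances must lie in [0, 1]")
    return float(np.sqrt((v ** 2).sum()))


def net_average_change(mean_ra) -> float:
    """Mean consecutive difference: (last - first) / (T - 1)."""
    v = np.asarray(mean_ra, dtype=float)
    if v.size < 2:
        raise ValueError("net_average_change requires >= 2 time points")
    return float((v[-1] - v[0]) / (v.size - 1))


def mean_ra_by_timepoint(table: FeatureTable, metadata: SampleMetadata,
                         niche: str) -> pd.DataFrame:
    """Features x time points matrix of mean per-sample relative abundance.

    The mean is taken over the niche's samples at each time point (mean of
    per-sample fractions, not a pooled-count ratio, so deep samples do not
    dominate).
    """
    samples = metadata.niche_samples(niche)
    samples = [s for s in samples if s in set(table.sample_ids)]
    if not samples:
        raise ValidationError(f"niche {niche!r} has no samples in the table")
    sub = table.subset_samples(samples)
    rel = relative_abundance(sub)
    tps = metadata.data.loc[samples, "time_point"]
    out = rel.groupby(tps).mean().T  # features x time points
    out.columns = [int(c) for c in out.columns]
    return out[sorted(out.columns)]


def volatility_records(mean_ra: pd.DataFrame, level: str) -> pd.DataFrame:
    """Importance and net change per feature; all-zero profiles are dropped.

    Features never observed in the niche carry no temporal signal and are
    excluded before any top-k selection.
    """
    active = mean_ra.loc[mean_ra.sum(axis=1) > 0]
    dropped = len(mean_ra) - len(active)
    if dropped:
        logger.debug("volatility: %d all-zero %s profiles excluded", dropped, level)
    recs = pd.DataFrame({
        "level": level,
        "importance": [importance(row) for row in active.to_numpy()],
        "net_change": [net_average_change(row) for row in active.to_numpy()],
        "mean_ra": active.mean(axis=1),
    }, index=active.index)
    recs.index.name = "feature_id"
    return recs


def _top_k(recs: pd.DataFrame, k: int, by: str, ascending: bool = False) -> list[str]:
    """Deterministic top-k: primary key, then importance desc, then id."""
    if len(recs) < k:
        logger.debug("volatility: quota %d exceeds supply %d", k, len(recs))
    keys, asc = [by], [ascending]
    if by != "importance":
        keys.append("importance")
        asc.append(False)
    keys.append("feature_id")
    asc.append(True)
    ordered = recs.sort_values(keys, ascending=asc, kind="mergesort")
    return list(ordered.index[:k])


def curate_features(asv_records: pd.DataFrame, taxon_records: pd.DataFrame,
                    taxonomy: TaxonomyMap) -> list[tuple[str, str]]:
    """Curated (feature_id, level) cohort for the succession heatmap.

    Union, in order: top-15 ASVs and top-15 taxa by importance; top-5
    increasing and top-5 decreasing ASVs, then taxa, by net change; for every
    included taxon its two most abundant ASVs (mean relative abundance over
    all time points) when not already present; and for every included ASV its
    parent taxon.  Deduplicated, deterministic under input-order shuffling
    (ties break by importance then identifier).
    """
    def _indexed(recs: pd.DataFrame) -> pd.DataFrame:
        recs = recs.reset_index().set_index("feature_id", drop=False)
        recs.index.name = None
        return recs

    asv_records = _indexed(asv_records)
    taxon_records = _indexed(taxon_records)

    chosen: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()

    def add(fid: str, level: str) -> None:
        key = (fid, level)
        if key not in seen:
            seen.add(key)
            chosen.append(key)

    for fid in _top_k(asv_records, QUOTA_IMPORTANCE, "importance"):
        add(fid, "asv")
    for fid in _top_k(taxon_records, QUOTA_IMPORTANCE, "importance"):
        add(fid, "taxon")
    for fid in _top_k(asv_records, QUOTA_TREND, "net_change", ascending=False):
        add(fid, "asv")
    for fid in _top_k(asv_records, QUOTA_TREND, "net_change", ascending=True):
        add(fid, "asv")
    for fid in _top_k(taxon_records, QUOTA_TREND, "net_change", ascending=False):
        add(fid, "taxon")
    for fid in _top_k(taxon_records, QUOTA_TREND, "net_change", ascending=True):
        add(fid, "taxon")

    # two most abundant ASVs of every included taxon
    parent = {fid: taxonomy.lowest_level(fid) for fid in asv_records.index}
    for taxon in [f for f, lvl in list(chosen) if lvl == "taxon"]:
        members = asv_records.loc[[f for f in asv_records.index
                                   if parent[f] == taxon]]
        ordered = members.sort_values(["mean_ra", "importance", "feature_id"],
                                      ascending=[False, False, True],
                                      kind="mergesort")
        for fid in ordered.index[:QUOTA_TAXON_ASVS]:
            add(fid, "asv")

    # closure: every curated ASV's taxon is curated
    for fid in [f for f, lvl in list(chosen) if lvl == "asv"]:
        taxon = parent[fid]
        if taxon in taxon_records.index:
            add(taxon, "taxon")
        else:  # taxon had an all-zero profile yet its ASV did not: impossible,
            raise ValidationError(   # the taxon profile is the sum of its ASVs'
                f"taxon {taxon!r} missing from taxon records")
    return chosen


@dataclass
class HeatmapBundle:
    """Three aligned heatmap layers plus row annotations.

    Rows interleave taxa and their curated ASVs: taxa sorted by peaking time
    point (ascending), each immediately followed by its ASVs.  ``ra`` holds
    mean relative abundances (taxon rows: the taxon's; ASV rows: the ASV's
    own).  ``ran`` is each ASV's share of its taxon's reads per time point
    (taxon rows are exactly 1 wherever the taxon is observed).  ``temporal``
    is each row's profile divided by its peak; all-zero rows are flagged
    rather than divided.
    """

    rows: pd.DataFrame       # row_id, level, taxon, peak_timepoint, zero_profile
    ra: pd.DataFrame
    ran: pd.DataFrame
    temporal: pd.DataFrame

    def write(self, outdir) -> list:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in [("rows", self.rows), ("heatmap_ra", self.ra),
                         ("heatmap_ran", self.ran),
                         ("heatmap_temporal", self.temporal)]:
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index_label="row_id", float_format="%.10g")
            paths.append(p)
        return paths


def heatmap_bundle(curated: list[tuple[str, str]], table: FeatureTable,
                   taxonomy: TaxonomyMap, metadata: SampleMetadata,
                   niche: str) -> HeatmapBundle:
    """Assemble the succession heatmap layers for one niche."""
    if not curated:
        raise ValueError("curated feature list is empty")
    asv_ra = mean_ra_by_timepoint(table, metadata, niche)
    taxon_table = collapse_by_lowest_taxon(table, taxonomy)
    taxon_ra = mean_ra_by_timepoint(taxon_table, metadata, niche)
    tps = list(asv_ra.columns)

    curated_taxa = [f for f, lvl in curated if lvl == "taxon"]
    curated_asvs = [f for f, lvl in curated if lvl == "asv"]
    parent = {a: taxonomy.lowest_level(a) for a in curated_asvs}
    orphans = sorted(set(parent.values()) - set(curated_taxa))
    if orphans:
        raise ValidationError(f"curated ASVs with uncurated taxa: {orphans}")

    def profile(fid: str, level: str) -> np.ndarray:
        src = taxon_ra if level == "taxon" else asv_ra
        if fid in src.index:
            return src.loc[fid].to_numpy(dtype=float)
        return np.zeros(len(tps))

    def peak(fid: str, level: str) -> int:
        v = profile(fid, level)
        return int(tps[int(np.argmax(v))])

    # taxa by peaking time point, ties by mean abundance (desc) then name
    taxa_sorted = sorted(
        curated_taxa,
        key=lambda t: (peak(t, "taxon"), -profile(t, "taxon").mean(), t))

    row_ids, rows = [], []
    ra_rows, ran_rows, temp_rows = [], [], []
    for taxon in taxa_sorted:
        tprof = profile(taxon, "taxon")
        members = sorted((a for a in curated_asvs if parent[a] == taxon),
                         key=lambda a: (-profile(a, "asv").mean(), a))
        for fid, level, prof in (
                [(taxon, "taxon", tprof)] +
                [(a, "asv", profile(a, "asv")) for a in members]):
            zero = not prof.any()
            if level == "taxon":
                ran = np.where(tprof > 0, 1.0, 0.0)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    ran = np.where(tprof > 0, prof / np.where(tprof > 0, tprof, 1.0), 0.0)
            temporal = prof / prof.max() if not zero else prof.copy()
            row_id = f"{level}:{fid}"
            row_ids.append(row_id)
            rows.append({"feature_id": fid, "level": level, "taxon": taxon,
                         "peak_timepoint": peak(fid, level),
                         "zero_profile": zero})
            ra_rows.append(prof)
            ran_rows.append(ran)
            temp_rows.append(temporal)

    cols = [f"t{t}" for t in tps]
    index = pd.Index(row_ids, name="row_id")
    return HeatmapBundle(
        rows=pd.DataFrame(rows, index=index),
        ra=pd.DataFrame(np.asarray(ra_rows), index=index, columns=cols),
        ran=pd.DataFrame(np.asarray(ran_rows), index=index, columns=cols),
        temporal=pd.DataFrame(np.asarray(temp_rows), index=index, columns=cols),
    )


def volatility_analysis(table: FeatureTable, metadata: SampleMetadata,
                        taxonomy: TaxonomyMap, niche: str):
    """Records, curated cohort and heatmap bundle for one niche."""
    asv_ra = mean_ra_by_timepoint(table, metadata, niche)
    taxon_table = collapse_by_lowest_taxon(table, taxonomy)
    taxon_ra = mean_ra_by_timepoint(taxon_table, metadata, niche)
    asv_recs = volatility_records(asv_ra, "asv")
    taxon_recs = volatility_records(taxon_ra, "taxon")
    curated = curate_features(asv_recs, taxon_recs, taxonomy)
    bundle = heatmap_bundle(curated, table, taxonomy, metadata, niche)
    return asv_recs, taxon_recs, curated, bundle
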