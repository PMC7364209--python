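"""Domain types, file I/O and table transforms.

The central object is :class:`FeatureTable`, a dense samples x features matrix
of sequencing read counts (non-negative integers).  Around it live the
:class:`TaxonomyMap` (feature -> ranked lineage, with a derived "lowest
available level" used for taxon collapsing and congeneric grouping), the
:class:`SampleMetadata` (niche, time point, plant of origin) and a rooted,
branch-length-bearing phylogeny handled as a :class:`skbio.TreeNode`.

File formats are deliberately plain: TSV for tables/taxonomy/metadata
(including the BIOM-TSV dialect with a leading ``#OTU ID`` header) and newick
for trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed objects violate a cross-reference or type invariant."""


class EmptyResultError(ValueError):
    """An operation removed every sample (or feature) from a table."""


#: The four habitats sampled in a root-knot-nematode infection time course.
NICHES = ("rhizosphere_soil", "root", "gall", "J2")

#: Read-depth threshold below which samples are excluded (inclusive boundary:
#: a sample with exactly this many reads is kept).
DEFAULT_MIN_DEPTH = 8828

_SAMPLE_KEYWORDS = {"sample_id", "sample-id", "#sampleid", "sample id", "sample"}
_FEATURE_KEYWORDS = {"#otu id", "#otuid", "feature_id", "feature-id", "feature id",
                     "asv_id", "asv-id", "asv", "feature", "otu"}


@dataclass(frozen=True)
class GroupKey:
    """A (niche, time point) subset of samples."""

    niche: str
    time_point: int

    def __str__(self) -> str:  # used in output tables and error messages
        return f"{self.niche}@t{self.time_point}"


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Samples x features matrix of read counts.

    Parameters
    ----------
    data:
        DataFrame indexed by sample identifiers with feature identifiers as
        columns.  Values must be non-negative integers; every sample must have
        a positive total.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate feature identifiers: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=1e-9):
                raise FormatError("feature table contains non-integer counts")
            df = df.round().astype(np.int64)
        else:
            df = df.astype(np.int64, copy=False)
        if (df.to_numpy() < 0).any():
            bad = df.index[(df < 0).any(axis=1)].tolist()
            raise FormatError(f"negative counts in samples: {bad}")
        totals = df.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total count: {empty}")
        object.__setattr__(self, "data", df)

    # -- basic accessors ----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def depths(self) -> pd.Series:
        """Total read count per sample."""
        return self.data.sum(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"unknown sample identifiers: {missing}")
        return FeatureTable(self.data.loc[list(sample_ids)])

    def presence(self) -> pd.DataFrame:
        """Boolean samples x features presence (count > 0) matrix."""
        return self.data > 0

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, orientation: str = "auto") -> "FeatureTable":
        """Read a feature table from TSV.

        ``orientation`` is ``"samples"`` (samples x features),
        ``"features"`` (features x samples, the BIOM-TSV convention) or
        ``"auto"``, which inspects the first header cell: sample-like
        keywords mean rows are samples, feature-like keywords (including
        ``#OTU ID``) mean rows are features.
        """
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            # BIOM TSV exports may carry a comment line before the header
            def _is_header(line: str) -> bool:
                key = line.split("\t")[0].strip().lower()
                return key in _FEATURE_KEYWORDS or key in _SAMPLE_KEYWORDS
            while first.startswith("#") and not _is_header(first):
                first = fh.readline()
            header_key = first.split("\t")[0].strip().lower()
            try:
                df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
            except Exception as exc:  # pragma: no cover - pandas error detail
                raise FormatError(f"{path}: could not parse TSV ({exc})") from None
        cols = [c.strip() for c in first.rstrip("\n").split("\t")[1:]]
        if df.shape[1] != len(cols):
            raise FormatError(f"{path}: header declares {len(cols)} columns, "
                              f"rows have {df.shape[1]}")
        df.columns = cols
        df.index = df.index.astype(str)
        df.index.name = None
        df.columns.name = None
        if orientation == "auto":
            if header_key in _SAMPLE_KEYWORDS:
                orientation = "samples"
            elif header_key in _FEATURE_KEYWORDS:
                orientation = "features"
            else:
                raise FormatError(
                    f"{path}: cannot auto-detect orientation from header "
                    f"keyword {first.split(chr(9))[0]!r}; pass orientation=")
        if orientation == "features":
            df = df.T
        elif orientation != "samples":
            raise ValueError(f"unknown orientation {orientation!r}")
        non_numeric = df.columns[~df.apply(
            lambda col: pd.to_numeric(col, errors="coerce").notna().all())]
        if len(non_numeric):
            raise FormatError(f"{path}: non-numeric values in {list(non_numeric)}")
        return cls(df.apply(pd.to_numeric))

    def to_tsv(self, path: str | Path, orientation: str = "samples") -> None:
        path = Path(path)
        if orientation == "samples":
            self.data.to_csv(path, sep="\t", index_label="sample_id")
        elif orientation == "features":
            self.data.T.to_csv(path, sep="\t", index_label="#OTU ID")
        else:
            raise ValueError(f"unknown orientation {orientation!r}")


# ---------------------------------------------------------------------------
# TaxonomyMap
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyMap:
    """Feature -> ranked lineage, with a derived lowest available level.

    The lowest available taxonomic level of a feature is the last rank label
    in its lineage that is non-empty and not a configured placeholder token.
    By default every non-empty string counts as informative.
    """

    lineages: dict[str, tuple[str, ...]]
    placeholders: frozenset = frozenset()

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for fid, lineage in self.lineages.items():
            ranks = tuple(str(r).strip() for r in lineage)
            if not any(self._informative(r) for r in ranks):
                raise ValidationError(
                    f"feature {fid!r} has no informative rank in lineage {ranks}")
            clean[str(fid)] = ranks
        self.lineages = clean

    def _informative(self, rank: str) -> bool:
        if not rank:
            return False
        return rank not in self.placeholders

    def lowest_level(self, feature_id: str) -> str:
        """Last informative rank label of the feature's lineage."""
        try:
            lineage = self.lineages[feature_id]
        except KeyError:
            raise ValidationError(f"no taxonomy for feature {feature_id!r}") from None
        for rank in reversed(lineage):
            if self._informative(rank):
                return rank
        raise ValidationError(f"feature {feature_id!r}: lineage uninformative")

    def display_name(self, feature_id: str) -> str:
        """Human-readable ``lowest-level|digest`` display name."""
        return f"{self.lowest_level(feature_id)}|{feature_id}"

    def covers(self, feature_ids: Iterable[str]) -> list[str]:
        """Return the feature ids NOT covered by this taxonomy."""
        return [f for f in feature_ids if f not in self.lineages]

    @classmethod
    def from_tsv(cls, path: str | Path, placeholders: Iterable[str] = ()) -> "TaxonomyMap":
        path = Path(path)
        lineages: dict[str, tuple[str, ...]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                key = parts[0].strip()
                if lineno == 1 and key.lower() in {"feature_id", "feature-id",
                                                   "feature id", "#otu id", "taxon"}:
                    continue
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 columns")
                lineage = tuple(tok.strip() for tok in parts[1].split(";"))
                if key in lineages:
                    raise FormatError(f"{path}:{lineno}: duplicate feature {key!r}")
                lineages[key] = lineage
        return cls(lineages, frozenset(placeholders))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\tlineage\n")
            for fid, lineage in self.lineages.items():
                fh.write(f"{fid}\t{'; '.join(lineage)}\n")


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample niche, time point and plant of origin."""

    data: pd.DataFrame  # index sample_id; columns niche, time_point, plant_id

    REQUIRED = ("niche", "time_point", "plant_id")

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in self.REQUIRED if c not in df.columns]
        if missing_cols:
            raise FormatError(f"metadata missing required columns: {missing_cols}")
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if df["niche"].isna().any() or (df["niche"].astype(str).str.strip() == "").any():
            raise ValidationError("metadata contains samples with missing niche")
        tp = pd.to_numeric(df["time_point"], errors="coerce")
        if tp.isna().any():
            bad = df.index[tp.isna()].tolist()
            raise ValidationError(f"non-integer time_point for samples: {bad}")
        if (tp < 1).any():
            raise ValidationError("time_point values must be >= 1")
        df = df.copy()
        df["time_point"] = tp.astype(int)
        df["niche"] = df["niche"].astype(str)
        df["plant_id"] = df["plant_id"].astype(str)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def niches(self) -> list[str]:
        """Niches in canonical order (known niches first), then alphabetical."""
        present = set(self.data["niche"])
        ordered = [n for n in NICHES if n in present]
        ordered += sorted(present - set(NICHES))
        return ordered

    @property
    def time_points(self) -> list[int]:
        return sorted(self.data["time_point"].unique())

    def group(self, key: GroupKey) -> list[str]:
        """Sample ids belonging to one (niche, time point) group."""
        mask = (self.data["niche"] == key.niche) & (self.data["time_point"] == key.time_point)
        return list(self.data.index[mask])

    def niche_samples(self, niche: str) -> list[str]:
        return list(self.data.index[self.data["niche"] == niche])

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except Exception as exc:
            raise FormatError(f"{path}: could not parse TSV ({exc})") from None
        if "sample_id" not in df.columns:
            raise FormatError(f"{path}: missing required column sample_id")
        df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def validate_tree(tree: TreeNode) -> TreeNode:
    """Check branch lengths (finite, >= 0) and tip-name uniqueness.

    Branch lengths of ``None`` (commonly the root) are set to 0 so downstream
    arithmetic never sees missing values.
    """
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        seen, dup = set(), set()
        for n in names:
            (dup if n in seen else seen).add(n)
        raise ValidationError(f"duplicate tip names in tree: {sorted(dup)}")
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        if not math.isfinite(node.length) or node.length < 0:
            raise ValidationError(
                f"invalid branch length {node.length!r} at node {node.name!r}")
    return tree


def read_tree(path: str | Path) -> TreeNode:
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"{path}: could not parse newick ({exc})") from None
    return validate_tree(tree)


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Dataset loading
# ---------------------------------------------------------------------------

def load_dataset(
    table_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
    tree_path: str | Path | None = None,
):
    """Load and cross-validate the four standard inputs.

    Returns ``(table, taxonomy, metadata, tree_or_None)``.  Features present
    in the table but absent from the taxonomy (or the tree, when given) and
    samples without metadata raise :class:`ValidationError` listing the
    offending identifiers.
    """
    table = FeatureTable.from_tsv(table_path)
    taxonomy = TaxonomyMap.from_tsv(taxonomy_path)
    metadata = SampleMetadata.from_tsv(metadata_path)
    tree = read_tree(tree_path) if tree_path is not None else None

    problems = []
    uncovered = taxonomy.covers(table.feature_ids)
    if uncovered:
        problems.append(f"features missing from taxonomy: {sorted(uncovered)}")
    missing_meta = [s for s in table.sample_ids if s not in metadata.data.index]
    if missing_meta:
        problems.append(f"samples missing from metadata: {sorted(missing_meta)}")
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        off_tree = [f for f in table.feature_ids if f not in tips]
        if off_tree:
            problems.append(f"features missing from tree: {sorted(off_tree)}")
    if problems:
        raise ValidationError("; ".join(problems))
    metadata = metadata.subset(table.sample_ids)
    return table, taxonomy, metadata, tree


# ---------------------------------------------------------------------------
# Table transforms
# ---------------------------------------------------------------------------

def filter_min_depth(table: FeatureTable, min_depth: int = DEFAULT_MIN_DEPTH,
                     prune_empty_features: bool = False) -> FeatureTable:
    """Drop samples whose total read count is below ``min_depth``.

    The boundary is inclusive: a sample with exactly ``min_depth`` reads is
    kept.  Features are untouched unless ``prune_empty_features`` is set, in
    which case features left with zero reads everywhere are removed too.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    keep = table.depths() >= min_depth
    if not keep.any():
        raise EmptyResultError(
            f"min_depth={min_depth} removes all {table.n_samples} samples")
    df = table.data.loc[keep]
    if prune_empty_features:
        df = df.loc[:, df.sum(axis=0) > 0]
    return FeatureTable(df)


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Per-sample relative abundances (each row sums to 1)."""
    totals = table.depths()
    if (totals == 0).any():  # unreachable through FeatureTable, kept for raw frames
        raise ValueError("sample with zero total count")
    return table.data.div(totals, axis=0)


def collapse_by_lowest_taxon(table: FeatureTable, taxonomy: TaxonomyMap) -> FeatureTable:
    """Sum ASV counts into taxa defined by the lowest available rank.

    Per-sample totals are conserved exactly (integer arithmetic).  Output
    features (taxa) are ordered lexicographically for determinism.
    """
    uncovered = taxonomy.covers(table.feature_ids)
    if uncovered:
        raise ValidationError(f"features missing from taxonomy: {sorted(uncovered)}")
    mapping = {f: taxonomy.lowest_level(f) for f in table.feature_ids}
    collapsed = table.data.T.groupby(table.data.columns.map(mapping)).sum().T
    collapsed = collapsed[sorted(collapsed.columns)]
    return FeatureTable(collapsed)


def subsample_groups(
    table: FeatureTable,
    metadata: SampleMetadata,
    seed: int,
    time_points: Sequence[int] | None = None,
    niches: Sequence[str] | None = None,
):
    """Balance sample counts across niches within each time point.

    For every time point, the niche with the fewest samples sets the quota and
    every other niche is down-sampled (uniformly, without replacement) to it.
    Selection is reproducible from ``seed``.  Returns the balanced
    ``(FeatureTable, SampleMetadata)`` pair.
    """
    rng = np.random.default_rng(seed)
    tps = list(time_points) if time_points is not None else metadata.time_points
    wanted_niches = list(niches) if niches is not None else metadata.niches
    kept: list[str] = []
    for tp in sorted(tps):
        groups = {n: metadata.group(GroupKey(n, tp)) for n in wanted_niches}
        groups = {n: s for n, s in groups.items() if s}
        if not groups:
            continue
        quota = min(len(s) for s in groups.values())
        for niche in wanted_niches:
            samples = groups.get(niche)
            if not samples:
                continue
            chosen = rng.choice(len(samples), size=quota, replace=False)
            kept.extend(samples[i] for i in sorted(chosen))
    if not kept:
        raise EmptyResultError("no samples left after group subsampling")
    kept = [s for s in table.sample_ids if s in set(kept)]  # stable order
    return table.subset_samples(kept), metadata.subset(kept)
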