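"""End-to-end orchestration of the analysis stages.

``run_all`` executes: (simulate or load) -> depth filter -> taxon collapse ->
alpha diversity with per-time-point gall-vs-root Kruskal-Wallis tests ->
UniFrac beta diversity with PCoA/biplot, per-time-point gall-vs-root Wilcoxon
and PERMANOVA -> core/unique drift analysis (raw and sample-size-normalized)
-> congeneric patristic distances -> per-niche feature volatility.  Every
stochastic step derives its stream from the single run seed; a manifest of
output files with SHA-256 checksums closes the run, so identical configs and
seeds produce byte-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import congeneric as cg
from . import core_drift as cd
from . import volatility as vol
from .data_model import (DEFAULT_MIN_DEPTH, FeatureTable, GroupKey,
                         SampleMetadata, TaxonomyMap, collapse_by_lowest_taxon,
                         filter_min_depth, load_dataset, relative_abundance)
from .diversity import alpha_diversity, biplot_loadings, pcoa, unifrac
from .stats import (bh_adjust, kruskal_wallis, permanova,
                    wilcoxon_signed_rank)
from .synthetic import GeneratorConfig, write_dataset

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run."""

    output_dir: str = "nemacore_out"
    # either explicit input paths ...
    table_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    # ... or a generator config (used when table_path is None)
    generator: GeneratorConfig | None = None
    min_depth: int = DEFAULT_MIN_DEPTH
    drift_time_points: tuple = cd.DEFAULT_TIME_POINTS
    n_permutations: int = 999
    alpha_level: float = 0.05
    seed: int = 0
    volatility_niches: tuple = ("root", "gall", "J2")
    run_unifrac: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in raw.items()})
        if gen is not None:
            gen = {k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
                       if isinstance(v, list) else v) for k, v in gen.items()}
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        # the target directory is not part of the run's scientific identity;
        # omitting it keeps output trees byte-identical across locations
        data.pop("output_dir", None)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True, default_flow_style=False)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path, index_label=None) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
              index=index_label is not None, index_label=index_label)
    return path


def _dm_to_tsv(dm, path: Path) -> Path:
    df = pd.DataFrame(np.asarray(dm.data), index=list(dm.ids), columns=list(dm.ids))
    return _write(df, path, index_label="sample_id")


def run_all(config: PipelineConfig):
    """Run the full pipeline; returns the output directory path.

    Halts with :class:`StageError` naming the failing stage; everything
    written before the failure stays on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    written: list[Path] = [out / "resolved_config.yaml"]
    seed = int(config.seed)

    stage = "load"
    try:
        if config.table_path is not None:
            if config.taxonomy_path is None or config.metadata_path is None:
                raise ValueError("table_path requires taxonomy_path and metadata_path")
            table, taxonomy, metadata, tree = load_dataset(
                config.table_path, config.taxonomy_path,
                config.metadata_path, config.tree_path)
        else:
            gen = config.generator or GeneratorConfig(seed=seed)
            data_dir = out / "dataset"
            table, taxonomy, metadata, tree = write_dataset(gen, data_dir)
            written += sorted(data_dir.iterdir())
        if tree is None and config.run_unifrac:
            raise ValueError("UniFrac/Faith's PD requested but no tree was "
                             "provided (tree_path is missing)")

        stage = "depth_filter"
        table = filter_min_depth(table, config.min_depth)
        metadata = metadata.subset(table.sample_ids)
        table.to_tsv(out / "filtered_table.tsv")
        written.append(out / "filtered_table.tsv")

        stage = "alpha"
        alpha = alpha_diversity(table, tree)
        written.append(_write(alpha, out / "alpha_diversity.tsv", "sample_id"))
        written.append(_write(_alpha_tests(alpha, metadata),
                              out / "alpha_tests.tsv"))

        stage = "beta"
        if config.run_unifrac:
            dm_u = unifrac(table, tree, "unweighted")
            dm_w = unifrac(table, tree, "weighted")
            written.append(_dm_to_tsv(dm_u, out / "unifrac_unweighted.tsv"))
            written.append(_dm_to_tsv(dm_w, out / "unifrac_weighted.tsv"))
            rel = relative_abundance(table)
            for name, dm in (("unweighted", dm_u), ("weighted", dm_w)):
                ordn = pcoa(dm)
                ordn.features = biplot_loadings(ordn, rel, n_features=25)
                written += [Path(p) for p in ordn.write(out / f"pcoa_{name}")]
            written.append(_write(
                _beta_tests(dm_w, metadata, config.n_permutations, seed),
                out / "beta_tests.tsv"))

        stage = "drift"
        drift_dir = out / "drift"
        for normalize in (False, True):
            res = cd.drift_analysis(table, metadata, taxonomy,
                                    time_points=config.drift_time_points,
                                    normalize=normalize, seed=seed)
            tag = "normalized" if normalize else "raw"
            written.append(_write(res.r_table, drift_dir / f"r_values_{tag}.tsv"))
            written.append(_write(res.comparisons,
                                  drift_dir / f"comparisons_{tag}.tsv"))
            if not normalize:
                written.append(_write(cd.core_sets_table(res.core_sets),
                                      drift_dir / "core_sets.tsv"))

        stage = "congeneric"
        sets = cg.congeneric_analysis(table, metadata, taxonomy, tree,
                                      time_points=config.drift_time_points)
        cg_dir = out / "congeneric"
        written.append(_write(cg.pairs_table(sets), cg_dir / "pairs.tsv"))
        written.append(_write(cg.compare_congeneric_distributions(sets),
                              cg_dir / "comparisons.tsv"))

        stage = "volatility"
        for niche in config.volatility_niches:
            if not metadata.niche_samples(niche):
                logger.info("volatility: niche %s absent, skipped", niche)
                continue
            asv_recs, taxon_recs, curated, bundle = vol.volatility_analysis(
                table, metadata, taxonomy, niche)
            vdir = out / "volatility" / niche
            written.append(_write(asv_recs, vdir / "records_asv.tsv",
                                  "feature_id"))
            written.append(_write(taxon_recs, vdir / "records_taxon.tsv",
                                  "feature_id"))
            written.append(_write(
                pd.DataFrame(curated, columns=["feature_id", "level"]),
                vdir / "curated.tsv"))
            written += [Path(p) for p in bundle.write(vdir)]
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = _manifest(out, written)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    logger.info("run complete: %d outputs in %s", len(manifest), out)
    return out


def _alpha_tests(alpha: pd.DataFrame, metadata: SampleMetadata) -> pd.DataFrame:
    """Gall-vs-root Kruskal-Wallis per time point and metric, BH per metric."""
    rows = []
    for metric in alpha.columns:
        fam = []
        for tp in metadata.time_points:
            g = alpha.loc[metadata.group(GroupKey("gall", tp)), metric].dropna()
            r = alpha.loc[metadata.group(GroupKey("root", tp)), metric].dropna()
            if len(g) == 0 or len(r) == 0:
                continue
            res = kruskal_wallis(g, r)
            fam.append({"metric": metric, "time_point": tp,
                        "H": res.statistic, "p_value": res.p_value,
                        "n_gall": len(g), "n_root": len(r)})
        if fam:
            q = bh_adjust([f["p_value"] for f in fam])
            for f, qv in zip(fam, q):
                f["q_value"] = float(qv)
            rows.extend(fam)
    return pd.DataFrame(rows, columns=["metric", "time_point", "H", "p_value",
                                       "q_value", "n_gall", "n_root"])


def _beta_tests(dm, metadata: SampleMetadata, n_permutations: int,
                seed: int) -> pd.DataFrame:
    """Per-time-point root-vs-gall beta tests on a distance matrix.

    Two complementary views are reported per time point: a PERMANOVA on the
    niche labels of the root and gall samples, and a one-sample Wilcoxon of
    the within-plant root-gall distances against the median within-niche
    distance at that time point (the reference a paired distance would take
    if galls were just more root).  q-values correct each family separately.
    """
    ids = set(dm.ids)
    perm_rows, wil_rows = [], []
    for k, tp in enumerate(metadata.time_points):
        root = [s for s in metadata.group(GroupKey("root", tp)) if s in ids]
        gall = [s for s in metadata.group(GroupKey("gall", tp)) if s in ids]
        if len(root) < 2 or len(gall) < 2:
            continue
        both = root + gall
        sub = dm.filter(both)
        labels = ["root"] * len(root) + ["gall"] * len(gall)
        res = permanova(sub, labels, n_permutations=n_permutations,
                        seed=seed + 1000 + k)
        perm_rows.append({"test": "permanova", "time_point": tp,
                          "statistic": res.statistic, "p_value": res.p_value,
                          "n_root": len(root), "n_gall": len(gall)})
        # within-plant root-gall distances vs within-niche median
        plant = metadata.data["plant_id"]
        paired = []
        for rs in root:
            for gs in gall:
                if plant[rs] == plant[gs]:
                    paired.append(dm[rs, gs])
        within = [dm[a, b] for grp in (root, gall)
                  for i, a in enumerate(grp) for b in grp[i + 1:]]
        if paired and within:
            ref = float(np.median(within))
            res_w = wilcoxon_signed_rank(np.asarray(paired) - ref)
            wil_rows.append({"test": "wilcoxon_within_plant", "time_point": tp,
                             "statistic": res_w.statistic,
                             "p_value": res_w.p_value,
                             "n_root": len(root), "n_gall": len(gall),
                             "reference_median": ref})
    out = []
    for fam in (perm_rows, wil_rows):
        if fam:
            q = bh_adjust([f["p_value"] for f in fam])
            for f, qv in zip(fam, q):
                f["q_value"] = float(qv)
            out.extend(fam)
    return pd.DataFrame(out, columns=["test", "time_point", "statistic",
                                      "p_value", "q_value", "n_root", "n_gall",
                                      "reference_median"])


def _manifest(out: Path, written: list[Path]) -> pd.DataFrame:
    rows = []
    for path in sorted(set(written)):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        rows.append({"path": str(path.relative_to(out)), "sha256": digest,
                     "bytes": path.stat().st_size})
    return pd.DataFrame(rows, columns=["path", "sha256", "bytes"])
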