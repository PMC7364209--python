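import numpy as np
import pandas as pd
import pytest

from nemacore.data_model import (EmptyResultError, FeatureTable, FormatError,
                                 GroupKey, SampleMetadata, TaxonomyMap,
                                 ValidationError, collapse_by_lowest_taxon,
                                 filter_min_depth, load_dataset,
                                 relative_abundance, subsample_groups)
from nemacore.synthetic import GeneratorConfig, write_dataset


class TestFeatureTable:
    def test_rejects_negative_counts(self):
        with pytest.raises(FormatError, match="negative"):
            FeatureTable(pd.DataFrame([[1, -2]], index=["s"], columns=["a", "b"]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError, match="duplicate"):
            FeatureTable(pd.DataFrame([[1, 2], [1, 2]], index=["s", "s"],
                                      columns=["a", "b"]))

    def test_rejects_zero_total_sample(self):
        with pytest.raises(ValidationError, match="zero total"):
            FeatureTable(pd.DataFrame([[0, 0]], index=["s"], columns=["a", "b"]))

    @pytest.mark.parametrize("orientation", ["samples", "features"])
    def test_tsv_round_trip(self, toy_table, tmp_path, orientation):
        path = tmp_path / "t.tsv"
        toy_table.to_tsv(path, orientation=orientation)
        back = FeatureTable.from_tsv(path)  # orientation auto-detected
        pd.testing.assert_frame_equal(back.data, toy_table.data)

    def test_biom_dialect_header(self, tmp_path):
        path = tmp_path / "biom.tsv"
        path.write_text("# Constructed from biom file\n"
                        "#OTU ID\ts1\ts2\na\t1\t2\nb\t3\t4\n")
        t = FeatureTable.from_tsv(path)
        assert t.sample_ids == ["s1", "s2"]
        assert t.data.loc["s2", "b"] == 4

    def test_unknown_header_keyword_raises(self, tmp_path):
        path = tmp_path / "odd.tsv"
        path.write_text("whatever\ts1\na\t1\n")
        with pytest.raises(FormatError, match="orientation"):
            FeatureTable.from_tsv(path)


class TestDepthFilter:
    def test_inclusive_boundary_at_retention_threshold(self):
        # depths 8828 / 8827 / 30145: the sample at exactly the threshold stays
        counts = pd.DataFrame({"a": [8000, 8000, 30000], "b": [828, 827, 145]},
                              index=["keep_edge", "drop", "keep"])
        out = filter_min_depth(FeatureTable(counts), 8828)
        assert sorted(out.sample_ids) == ["keep", "keep_edge"]

    def test_zero_threshold_is_identity(self, toy_table):
        out = filter_min_depth(toy_table, 0)
        pd.testing.assert_frame_equal(out.data, toy_table.data)

    def test_all_removed_raises(self, toy_table):
        with pytest.raises(EmptyResultError):
            filter_min_depth(toy_table, 10 ** 9)

    def test_idempotent(self, toy_table):
        once = filter_min_depth(toy_table, 8)
        twice = filter_min_depth(once, 8)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_optional_feature_prune(self):
        counts = pd.DataFrame({"a": [10, 1], "b": [0, 5]}, index=["s1", "s2"])
        out = filter_min_depth(FeatureTable(counts), 7, prune_empty_features=True)
        assert out.feature_ids == ["a"]


class TestRelativeAbundance:
    def test_matches_hand_normalized_rows(self):
        t = FeatureTable(pd.DataFrame([[2, 3, 5], [1, 0, 1]],
                                      index=["s1", "s2"], columns=list("abc")))
        rel = relative_abundance(t)
        assert np.allclose(rel.loc["s1"], [0.2, 0.3, 0.5])
        assert np.allclose(rel.loc["s2"], [0.5, 0.0, 0.5])
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)


class TestCollapse:
    def test_sums_within_taxon_and_conserves_totals(self, toy_table, toy_taxonomy):
        out = collapse_by_lowest_taxon(toy_table, toy_taxonomy)
        # a1+a2 -> g__GenA; a3 -> g__GenB; a4 -> p__P2 (last informative rank)
        assert out.data.loc["s1", "g__GenA"] == 5
        assert out.data.loc["s2", "g__GenA"] == 5
        assert (out.depths() == toy_table.depths()).all()

    def test_matches_brute_force_group_sum(self, small_dataset):
        table, taxonomy, _, _ = small_dataset
        out = collapse_by_lowest_taxon(table, taxonomy)
        for taxon in out.feature_ids:
            members = [f for f in table.feature_ids
                       if taxonomy.lowest_level(f) == taxon]
            expected = table.data[members].sum(axis=1)
            assert (out.data[taxon] == expected).all()

    def test_all_distinct_taxa_is_renaming(self):
        t = FeatureTable(pd.DataFrame([[1, 2]], index=["s"], columns=["x", "y"]))
        tax = TaxonomyMap({"x": ("d__B", "g__G1"), "y": ("d__B", "g__G2")})
        out = collapse_by_lowest_taxon(t, tax)
        assert sorted(out.feature_ids) == ["g__G1", "g__G2"]
        assert out.data.to_numpy().sum() == 3

    def test_missing_taxonomy_rejected(self, toy_table):
        tax = TaxonomyMap({"a1": ("g__G",)})
        with pytest.raises(ValidationError, match="a2"):
            collapse_by_lowest_taxon(toy_table, tax)


class TestTaxonomyMap:
    def test_lowest_level_skips_empty_and_placeholder_ranks(self):
        tax = TaxonomyMap({"f": ("d__B", "g__G", "")},)
        assert tax.lowest_level("f") == "g__G"
        tax2 = TaxonomyMap({"f": ("d__B", "g__G", "uncultured")},
                           placeholders=frozenset({"uncultured"}))
        assert tax2.lowest_level("f") == "g__G"

    def test_display_name_prefixes_lowest_level(self):
        tax = TaxonomyMap({"abc123": ("d__B", "g__G")})
        assert tax.display_name("abc123") == "g__G|abc123"


class TestSubsampleGroups:
    def test_reduces_to_smallest_niche_per_time_point(self):
        rng = np.random.default_rng(0)
        rows, meta = [], []
        sizes = {"rhizosphere_soil": 16, "root": 9, "gall": 6, "J2": 8}
        for niche, n in sizes.items():
            for i in range(n):
                sid = f"{niche}.{i}"
                rows.append(pd.Series(rng.integers(1, 10, 5), name=sid))
                meta.append({"sample_id": sid, "niche": niche,
                             "time_point": 2, "plant_id": f"p{i}"})
        table = FeatureTable(pd.DataFrame(rows))
        md = SampleMetadata(pd.DataFrame(meta).set_index("sample_id"))
        sub_t, sub_m = subsample_groups(table, md, seed=1)
        per_niche = sub_m.data.groupby("niche").size()
        assert (per_niche == 6).all()

    def test_balanced_input_unchanged(self, small_dataset):
        table, _, md, _ = small_dataset
        sub_t, _ = subsample_groups(table, md, seed=5)
        assert sub_t.n_samples == table.n_samples

    def test_same_seed_same_selection(self, small_dataset):
        table, _, md, _ = small_dataset
        a, _ = subsample_groups(table, md, seed=9, niches=["gall"])
        b, _ = subsample_groups(table, md, seed=9, niches=["gall"])
        assert a.sample_ids == b.sample_ids


class TestLoadDataset:
    def test_round_trip_through_files(self, tmp_path):
        cfg = GeneratorConfig(n_genera=3, strains_per_genus=3,
                              samples_per_group=2, n_time_points=2,
                              depth=2000, missing_groups=(), seed=7)
        table, taxonomy, metadata, tree = write_dataset(cfg, tmp_path)
        t2, tax2, md2, tree2 = load_dataset(
            tmp_path / "feature_table.tsv", tmp_path / "taxonomy.tsv",
            tmp_path / "metadata.tsv", tmp_path / "tree.nwk")
        pd.testing.assert_frame_equal(t2.data, table.data)
        assert tax2.lineages == taxonomy.lineages
        pd.testing.assert_frame_equal(md2.data, metadata.data)
        assert {t.name for t in tree2.tips()} == {t.name for t in tree.tips()}

    def test_missing_taxonomy_feature_listed(self, tmp_path, toy_table,
                                             toy_metadata):
        toy_table.to_tsv(tmp_path / "t.tsv")
        toy_metadata.to_tsv(tmp_path / "m.tsv")
        (tmp_path / "tax.tsv").write_text(
            "a1\td__B; g__G\na2\td__B; g__G\na3\td__B; g__H\n")
        with pytest.raises(ValidationError, match="a4"):
            load_dataset(tmp_path / "t.tsv", tmp_path / "tax.tsv",
                         tmp_path / "m.tsv")


class TestSampleMetadata:
    def test_requires_columns(self):
        with pytest.raises(FormatError, match="plant_id"):
            SampleMetadata(pd.DataFrame({"niche": ["gall"], "time_point": [1]},
                                        index=["s"]))

    def test_group_lookup(self, toy_metadata):
        assert toy_metadata.group(GroupKey("gall", 2)) == ["s1", "s2"]
        assert toy_metadata.group(GroupKey("J2", 1)) == []
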