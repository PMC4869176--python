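"""Feature assignment precedence and fold enrichment."""

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

import methylseg as ms
from methylseg.annotation import DEFAULT_PRECEDENCE
from methylseg.errors import AnnotationError
from methylseg.io import GenomeAnnotation

from _oracles import stab_oracle


def site_frame(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions, "strand": "+",
                         "context": "CpG"})


def manual_annotation(chrom_sizes, features):
    """Assemble a GenomeAnnotation from raw per-label intervals (bypasses
    gene-model derivation; used to probe the enrichment formula directly)."""
    trees = {}
    for label, per_chrom in features.items():
        trees[label] = {}
        for chrom, ivs in per_chrom.items():
            t = IntervalTree()
            for s, e in ivs:
                t[s:e] = label
            trees[label][chrom] = t
    return GenomeAnnotation(chrom_sizes=chrom_sizes,
                            genes=pd.DataFrame(), features=features,
                            cpg_islands={}, feature_trees=trees,
                            gene_trees={}, island_trees={})


class TestAssignment:
    def test_site_within_2kb_of_tss_is_promoter(self, toy_annotation):
        fa = ms.assign_feature(("chr1", 98_500), toy_annotation)
        assert fa.feature == "promoter"

    def test_promoter_beats_exon_of_another_gene(self):
        genes = pd.DataFrame([
            {"chrom": "chr1", "tss": 100_000, "tes": 149_999, "strand": "+",
             "gene_id": "host", "exons": []},
            {"chrom": "chr1", "tss": 120_000, "tes": 160_000, "strand": "+",
             "gene_id": "nested", "exons": []},
        ])
        ann = ms.build_annotation(genes, pd.DataFrame(columns=["chrom", "start", "end"]),
                                  {"chr1": 1_000_000})
        # 119_000 is exonic for `host` but inside the promoter of `nested`
        fa = ms.assign_feature(("chr1", 119_000), ann)
        assert fa.feature == "promoter"
        assert fa.gene_ids == ("host",)

    def test_unfeatured_site_is_intergenic(self, toy_annotation):
        fa = ms.assign_feature(("chr1", 900_000), toy_annotation)
        assert fa.feature == "intergenic"
        assert not fa.intragenic

    def test_island_is_a_flag_not_a_label(self, toy_annotation):
        fa = ms.assign_feature(("chr1", 99_000), toy_annotation)
        assert fa.cpg_island
        assert fa.feature == "promoter"

    def test_unknown_chromosome_rejected(self, toy_annotation):
        with pytest.raises(AnnotationError):
            ms.assign_feature(("chrX", 10), toy_annotation)

    def test_matches_interval_stabbing_oracle(self):
        rng = np.random.default_rng(8)
        size = 500_000
        genes = pd.DataFrame([
            {"chrom": "chr1", "tss": int(s), "tes": int(s) + 19_999, "strand": "+",
             "gene_id": f"g{k}",
             "exons": [(int(s), int(s) + 5_000), (int(s) + 12_000, int(s) + 20_000)]}
            for k, s in enumerate(rng.integers(60_000, size - 80_000, 6))
        ])
        ann = ms.build_annotation(genes, pd.DataFrame(columns=["chrom", "start", "end"]),
                                  {"chr1": size})
        raw = {label: ann.features.get(label, {}).get("chr1", [])
               for label in DEFAULT_PRECEDENCE if label != "intergenic"}
        for pos in rng.integers(0, size, 1_000):
            got = ms.assign_feature(("chr1", int(pos)), ann).feature
            assert got == stab_oracle(int(pos), raw, DEFAULT_PRECEDENCE)


class TestEnrichment:
    def test_full_genome_feature_has_fold_one(self):
        ann = manual_annotation({"chr1": 10_000},
                                {"promoter": {"chr1": [(0, 10_000)]}})
        table = ms.enrichment_fold(site_frame([5, 500, 9_000]), ann,
                                   precedence=("promoter", "intergenic"))
        row = table.set_index("feature").loc["promoter"]
        assert row["fold"] == pytest.approx(1.0)

    def test_direct_formula_evaluation(self):
        # 10 of 100 sites inside a feature occupying 5% of the genome -> fold 2
        ann = manual_annotation({"chr1": 80_000},
                                {"promoter": {"chr1": [(0, 4_000)]}})
        positions = list(np.linspace(100, 3_900, 10).astype(int)) + \
            list(np.linspace(10_000, 79_000, 90).astype(int))
        table = ms.enrichment_fold(site_frame(positions), ann,
                                   precedence=("promoter", "intergenic"))
        by = table.set_index("feature")
        assert by.loc["promoter", "observed_pct"] == pytest.approx(10.0)
        assert by.loc["promoter", "expected_pct"] == pytest.approx(5.0)
        assert by.loc["promoter", "fold"] == pytest.approx(2.0)

    def test_zero_sites_is_an_error(self, toy_annotation):
        with pytest.raises(AnnotationError, match="skip enrichment"):
            ms.enrichment_fold(site_frame([]), toy_annotation)

    def test_absent_feature_reports_missing_fold(self):
        ann = manual_annotation({"chr1": 10_000},
                                {"promoter": {"chr1": [(0, 1_000)]}})
        table = ms.enrichment_fold(site_frame([100, 5_000]), ann,
                                   precedence=("promoter", "exon", "intergenic"))
        by = table.set_index("feature")
        assert np.isnan(by.loc["exon", "fold"])
        assert by.loc["exon", "observed_pct"] == 0.0

    def test_partition_conservation(self, toy_annotation):
        rng = np.random.default_rng(9)
        table = ms.enrichment_fold(site_frame(rng.integers(0, 1_000_000, 400)),
                                   toy_annotation)
        assert table["observed_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        ok = table["expected_pct"] > 0
        assert (table.loc[ok, "fold"] * table.loc[ok, "expected_pct"]).sum() == \
            pytest.approx(100.0, abs=1e-9)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(10)
        features = {
            "promoter": {"chr1": [(2_000, 6_000), (50_000, 52_000)]},
            "exon": {"chr1": [(4_000, 20_000), (70_000, 90_000)]},
        }
        scaled = {label: {"chr1": [(2 * s, 2 * e) for s, e in per["chr1"]]}
                  for label, per in features.items()}
        positions = rng.integers(0, 100_000, 300)
        prec = ("promoter", "exon", "intergenic")
        base = ms.enrichment_fold(site_frame(positions),
                                  manual_annotation({"chr1": 100_000}, features),
                                  precedence=prec)
        doubled = ms.enrichment_fold(site_frame(2 * positions),
                                     manual_annotation({"chr1": 200_000}, scaled),
                                     precedence=prec)
        assert np.allclose(base["fold"], doubled["fold"], equal_nan=True)


class TestGeneAssignment:
    def test_intragenic_region_lists_its_gene(self, toy_annotation):
        table, fraction = ms.assign_genes(
            pd.DataFrame([{"chrom": "chr1", "start": 120_000, "end": 120_200}]),
            toy_annotation)
        assert table.loc[0, "gene_ids"] == "geneA"
        assert bool(table.loc[0, "intragenic"])
        assert fraction == 1.0

    def test_intergenic_region_has_no_gene(self, toy_annotation):
        table, fraction = ms.assign_genes(
            pd.DataFrame([{"chrom": "chr1", "start": 900_000, "end": 900_200}]),
            toy_annotation)
        assert table.loc[0, "gene_ids"] == ""
        assert fraction == 0.0

    def test_region_overlapping_two_genes_lists_both(self):
        genes = pd.DataFrame([
            {"chrom": "chr1", "tss": 10_000, "tes": 29_999, "strand": "+",
             "gene_id": "g1", "exons": []},
            {"chrom": "chr1", "tss": 25_000, "tes": 44_999, "strand": "+",
             "gene_id": "g2", "exons": []},
        ])
        ann = ms.build_annotation(genes, pd.DataFrame(columns=["chrom", "start", "end"]),
                                  {"chr1": 100_000})
        table, _ = ms.assign_genes(
            pd.DataFrame([{"chrom": "chr1", "start": 26_000, "end": 28_000}]), ann)
        assert table.loc[0, "gene_ids"] == "g1;g2"

    def test_planted_intragenic_share_is_recovered(self, toy_annotation):
        # place 85% of 400 regions inside gene bodies, the rest far away
        rng = np.random.default_rng(13)
        inside = [(int(p), int(p) + 100)
                  for p in rng.integers(100_000, 139_000, 340)]
        outside = [(int(p), int(p) + 100)
                   for p in rng.integers(800_000, 990_000, 60)]
        regions = pd.DataFrame([{"chrom": "chr1", "start": s, "end": e}
                                for s, e in inside + outside])
        _, fraction = ms.assign_genes(regions, toy_annotation)
        assert fraction == pytest.approx(0.85, abs=3 * np.sqrt(0.85 * 0.15 / 400))
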