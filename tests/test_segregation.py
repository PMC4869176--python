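"""Region-set algebra, overlap significance and the propagation check."""

import numpy as np
import pandas as pd
import pytest

import methylseg as ms
from methylseg.errors import ConfigError, ConsistencyError

from _oracles import fisher_exact_oracle, overlap_pairs_oracle
from conftest import make_regions


class TestOverlapRegions:
    def test_partial_overlap_reported(self):
        pairs = ms.overlap_regions(make_regions([("chr1", 100, 300)]),
                                   make_regions([("chr1", 250, 400)]))
        assert len(pairs) == 1
        assert pairs.loc[0, "overlap_bp"] == 50

    def test_half_open_adjacency_is_not_overlap(self):
        pairs = ms.overlap_regions(make_regions([("chr1", 100, 200)]),
                                   make_regions([("chr1", 200, 300)]))
        assert len(pairs) == 0

    def test_min_overlap_threshold(self):
        a = make_regions([("chr1", 100, 300)])
        b = make_regions([("chr1", 250, 400)])
        assert len(ms.overlap_regions(a, b, min_overlap_bp=50)) == 1
        assert len(ms.overlap_regions(a, b, min_overlap_bp=51)) == 0

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            def random_set():
                regions, cur = [], 0
                for _ in range(int(rng.integers(0, 25))):
                    cur += int(rng.integers(1, 400))
                    end = cur + int(rng.integers(1, 300))
                    regions.append(("chr1" if rng.random() < 0.7 else "chr2",
                                    cur, end))
                    cur = end
                return regions

            a, b = random_set(), random_set()
            min_ov = int(rng.integers(1, 100))
            got = sorted(zip(*(ms.overlap_regions(make_regions(a), make_regions(b),
                                                  min_ov)[c] for c in
                               ("a_index", "b_index")))) if a and b else []
            assert got == overlap_pairs_oracle(a, b, min_ov)

    def test_symmetric_up_to_pair_order(self):
        a = make_regions([("chr1", 0, 500), ("chr1", 1000, 1500)])
        b = make_regions([("chr1", 400, 1100)])
        ab = ms.overlap_regions(a, b)
        ba = ms.overlap_regions(b, a)
        assert sorted(zip(ab["a_index"], ab["b_index"])) == \
            sorted(zip(ba["b_index"], ba["a_index"]))


class TestCandidateUniverse:
    def test_runs_of_tested_sites_become_regions(self):
        sites = pd.DataFrame({"chrom": "chr1",
                              "pos": [100, 200, 300, 400, 5000, 5100, 5200,
                                      5300, 20_000]})
        universe = ms.candidate_universe(sites, min_sites=4, max_gap=1000)
        assert list(universe.itertuples(index=False, name=None)) == [
            ("chr1", 100, 401), ("chr1", 5000, 5301)]


class TestFisherOverlap:
    @staticmethod
    def spaced_universe(n):
        return make_regions([("chr1", i * 1000, i * 1000 + 500) for i in range(n)])

    def test_counts_and_odds_ratio(self):
        universe = self.spaced_universe(100)
        a = universe.iloc[:20]
        b = pd.concat([universe.iloc[:10], universe.iloc[20:30]])
        res = ms.fisher_overlap_test(a, b, universe)
        assert (res.both, res.a_only, res.b_only, res.neither) == (10, 10, 10, 70)
        assert res.odds_ratio == pytest.approx(7.0)
        # p from exact enumeration of the 2x2 membership table
        assert res.p == pytest.approx(fisher_exact_oracle(10, 10, 10, 70), abs=1e-12)

    def test_no_shared_regions_gives_zero_odds(self):
        universe = self.spaced_universe(40)
        res = ms.fisher_overlap_test(universe.iloc[:10], universe.iloc[10:20],
                                     universe)
        assert res.both == 0
        assert res.odds_ratio == 0.0
        assert not res.odds_ratio_infinite

    def test_identical_sets_are_degenerate_with_p_one(self):
        universe = self.spaced_universe(30)
        sub = universe.iloc[:30]
        res = ms.fisher_overlap_test(sub, sub, universe)
        assert res.a_only == res.b_only == res.neither == 0
        assert res.odds_ratio_infinite
        assert res.p == pytest.approx(1.0)

    def test_universe_must_cover_both_sets(self):
        universe = self.spaced_universe(10)
        stray = make_regions([("chr1", 500_000, 500_100)])
        with pytest.raises(ConsistencyError):
            ms.fisher_overlap_test(stray, universe.iloc[:5], universe)

    def test_null_odds_ratio_median_near_one(self):
        rng = np.random.default_rng(18)
        universe = self.spaced_universe(200)
        odds = []
        for _ in range(200):
            a = universe.iloc[np.sort(rng.choice(200, 60, replace=False))]
            b = universe.iloc[np.sort(rng.choice(200, 60, replace=False))]
            odds.append(ms.fisher_overlap_test(a, b, universe).odds_ratio)
        assert 0.5 < float(np.median(odds)) < 2.0


class TestTraitSegregation:
    def test_constructive_case(self):
        collection = {"F1": make_regions([("chr1", 100, 300)]),
                      "F2": make_regions([("chr1", 250, 400)]),
                      "F3": make_regions([])}
        out = ms.trait_segregation(collection, ["F1", "F2"], ["F3"])
        assert list(out[["start", "end"]].itertuples(index=False, name=None)) == \
            [(100, 300)]
        assert out.loc[0, "supported_by"] == "F1;F2"

    def test_exclusion_by_absent_cohort(self):
        collection = {"F1": make_regions([("chr1", 100, 300)]),
                      "F2": make_regions([("chr1", 250, 400)]),
                      "F3": make_regions([("chr1", 260, 280)])}
        out = ms.trait_segregation(collection, ["F1", "F2"], ["F3"])
        assert len(out) == 0

    def test_single_present_cohort_is_identity(self):
        f2 = make_regions([("chr1", 10, 20), ("chr1", 500, 900)])
        out = ms.trait_segregation({"F2": f2}, ["F2"], [])
        assert list(out[["chrom", "start", "end"]].itertuples(index=False)) == \
            list(f2.itertuples(index=False))

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ConfigError, match="unknown cohort"):
            ms.trait_segregation({"F1": make_regions([])}, ["F1", "FX"], [])

    def test_gene_level_matching(self, toy_annotation):
        # both cohorts hit geneA through different, non-overlapping regions
        collection = {"F1": make_regions([("chr1", 101_000, 101_200)]),
                      "F2": make_regions([("chr1", 135_000, 135_200)])}
        region_mode = ms.trait_segregation(collection, ["F1", "F2"], [])
        gene_mode = ms.trait_segregation(collection, ["F1", "F2"], [],
                                         mode="gene", annotation=toy_annotation)
        assert len(region_mode) == 0
        assert len(gene_mode) == 1


class TestPropagation:
    @staticmethod
    def tables(meth_by_pos, n=1, coverage=30):
        rows = [("chr1", pos, "+", "CpG", m, coverage - m)
                for pos, m in meth_by_pos.items()]
        frame = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                            "meth", "unmeth"])
        return [frame.copy() for _ in range(n)]

    def test_identical_downstream_counts_do_not_propagate(self):
        region = make_regions([("chr1", 100, 400)])
        meth = {100: 20, 150: 20, 200: 20, 250: 20}
        table = ms.propagation_check(
            region, {"A": self.tables(meth, 2), "B": self.tables(meth, 2)})
        assert table.loc[0, "status"] == "tested"
        assert not table.loc[0, "propagates"]
        assert table.loc[0, "mean_diff"] == pytest.approx(0.0)

    def test_full_shift_propagates(self):
        region = make_regions([("chr1", 100, 400)])
        low = {100: 2, 150: 2, 200: 2, 250: 2}
        high = {100: 28, 150: 28, 200: 28, 250: 28}
        table = ms.propagation_check(
            region, {"A": self.tables(low, 2), "B": self.tables(high, 2)})
        assert bool(table.loc[0, "propagates"])
        assert table.loc[0, "n_dm_sites"] == 4

    def test_uncovered_region_is_untestable(self):
        regions = make_regions([("chr1", 100, 400), ("chr1", 9_000, 9_400)])
        meth = {100: 20, 150: 20, 200: 20, 250: 20}
        table = ms.propagation_check(
            regions, {"A": self.tables(meth, 2), "B": self.tables(meth, 2)})
        assert table.loc[1, "status"] == "untestable"
        assert table.loc[1, "propagates"] is None
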