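"""Integration bookkeeping: percents, persistence, concordance, overlaps."""
import numpy as np
import pytest

from epiconcord.concord import (
    deg_region_concordance,
    dhr_dmr_cooccurrence,
    percent,
    persistence,
    tissue_overlap,
)
from epiconcord.core import DEGRecord, Gene


def deg(gid, direction="up", fold=2.0, q=0.01, timepoint=""):
    ma, mb = (1.0, 2.0) if direction == "up" else (2.0, 1.0)
    return DEGRecord(gid, direction, fold, q, ma, mb, timepoint=timepoint)


def gene(gid, tss, chrom="chr1"):
    return Gene(gid, chrom, "+", tss, tss + 10_000)


class TestPercent:
    @pytest.mark.parametrize("k,n,expected", [
        (1850, 2162, 86), (1535, 1850, 83), (0, 7, 0), (7, 7, 100),
        (1, 200, 1), (1, 201, 0),
    ])
    def test_rounding_half_away_from_zero(self, k, n, expected):
        assert percent(k, n) == expected

    def test_undefined_for_zero_n(self):
        with pytest.raises(ValueError):
            percent(0, 0)

    def test_complement_sums_near_100(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 5000))
            k = int(rng.integers(0, n + 1))
            assert percent(k, n) + percent(n - k, n) in (99, 100, 101)


class TestPersistence:
    def test_disjoint_lists(self):
        res = persistence([deg("a"), deg("b")], [deg("c")])
        assert res.n_overlap == 0
        assert all(v == 0 for v in res.quadrants.values())

    def test_identical_lists(self):
        lst = [deg(f"g{i}", "up") for i in range(7)]
        res = persistence(lst, list(lst))
        assert res.n_overlap == 7
        assert res.quadrants["up_up"] == 7
        assert res.pct_same_direction == 100
        assert res.pct_overlap_of_t2 == 100

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            persistence([deg("a"), deg("a")], [deg("b")])

    def test_quadrants_track_direction_changes(self):
        t1 = [deg("a", "up"), deg("b", "up"), deg("c", "down"), deg("d", "down")]
        t2 = [deg("a", "up"), deg("b", "down"), deg("c", "up"), deg("e", "up")]
        res = persistence(t1, t2)
        assert res.quadrants == {"up_up": 1, "up_down": 1, "down_up": 1,
                                 "down_down": 0}
        assert res.n_overlap == 3
        assert res.pct_same_direction == percent(1, 3)


class TestDegRegionConcordance:
    def test_no_regions(self):
        genes = [gene("a", 50_000)]
        res = deg_region_concordance([deg("a")], [], genes)
        assert res.n_with_region == 0 and res.pct_expected is None

    def test_all_up_with_gain_at_10kb(self, region_factory):
        genes = [gene(f"g{i}", 300_000 * (i + 1)) for i in range(5)]
        degs = [deg(g.gene_id, "up") for g in genes]
        regions = [region_factory("chr1", g.tss + 9_500, g.tss + 10_500, "gain")
                   for g in genes]
        res = deg_region_concordance(degs, regions, genes, "positive",
                                     exclude_tss=True)
        assert res.n_with_region == 5
        assert res.pct_expected == 100
        inv = deg_region_concordance(degs, regions, genes, "inverse",
                                     exclude_tss=True)
        assert inv.pct_expected == 0

    def test_tss_exclusion_window(self, region_factory):
        g = gene("a", 500_000)
        close = region_factory("chr1", g.tss - 1_500, g.tss - 500, "loss")
        far = region_factory("chr1", g.tss + 20_000, g.tss + 21_000, "gain")
        with_tss = deg_region_concordance([deg("a", "up")], [close, far], [g],
                                          exclude_tss=False)
        without = deg_region_concordance([deg("a", "up")], [close, far], [g],
                                         exclude_tss=True)
        # nearest region wins when the TSS zone is included...
        assert with_tss.categories["up_loss"] == 1
        # ...but is ignored when excluded, leaving the enhancer gain
        assert without.categories["up_gain"] == 1

    def test_nearest_then_fold_then_gain_tiebreak(self, region_factory):
        g = gene("a", 500_000)
        left = region_factory("chr1", g.tss - 10_500, g.tss - 9_500, "loss",
                              fold=3.0)
        right = region_factory("chr1", g.tss + 9_500, g.tss + 10_500, "gain",
                               fold=5.0)
        res = deg_region_concordance([deg("a", "up")], [left, right], [g],
                                     exclude_tss=True)
        assert res.categories["up_gain"] == 1  # equidistant, larger fold wins

    def test_missing_gene_annotation_rejected(self, region_factory):
        with pytest.raises(KeyError):
            deg_region_concordance([deg("zzz")], [], [gene("a", 1_000)])

    def test_counts_invariant_to_input_order(self, rng, region_factory):
        genes = [gene(f"g{i}", 250_000 * (i + 1)) for i in range(3)]
        degs = [deg("g0", "up"), deg("g1", "down"), deg("g2", "up")]
        regions = [
            region_factory("chr1", 250_000 + 30_000, 250_000 + 31_000, "gain"),
            region_factory("chr1", 500_000 - 40_000, 500_000 - 39_000, "loss"),
            region_factory("chr1", 750_000 + 8_000, 750_000 + 9_000, "loss"),
        ]
        base = deg_region_concordance(degs, regions, genes, exclude_tss=True)
        perm = deg_region_concordance(list(reversed(degs)),
                                      list(reversed(regions)),
                                      list(reversed(genes)), exclude_tss=True)
        assert base == perm


class TestDhrDmrCooccurrence:
    def test_disjoint(self, region_factory):
        dhrs = [region_factory("chr1", 0, 1_000, "gain")]
        dmrs = [region_factory("chr1", 5_000, 6_000, "loss", mark="MBD")]
        res = dhr_dmr_cooccurrence(dhrs, dmrs)
        assert res["n_overlapping"] == 0 and res["pct_expected"] is None

    def test_inverse_coupling_is_expected(self, region_factory):
        dhrs = [region_factory("chr1", i * 10_000, i * 10_000 + 1_000, "gain")
                for i in range(4)]
        dmrs = [region_factory("chr1", i * 10_000 + 500, i * 10_000 + 1_500,
                               "loss", mark="MBD") for i in range(4)]
        res = dhr_dmr_cooccurrence(dhrs, dmrs)
        assert res["n_overlapping"] == 4
        assert res["combinations"]["gain_loss"] == 4
        assert res["pct_expected"] == 100

    def test_matches_bruteforce_largest_overlap_oracle(self, rng, genome,
                                                       random_region_factory):
        dhrs = random_region_factory(rng, genome, 150)
        dmrs = random_region_factory(rng, genome, 150, mark="MBD")
        res = dhr_dmr_cooccurrence(dhrs, dmrs)
        combos = {"gain_gain": 0, "gain_loss": 0, "loss_gain": 0, "loss_loss": 0}
        n_overlapping = 0
        for dhr in dhrs:
            cands = []
            for j, dmr in enumerate(dmrs):
                if dmr.chrom != dhr.chrom:
                    continue
                ov = min(dhr.end, dmr.end) - max(dhr.start, dmr.start)
                if ov >= 1:
                    cands.append((-ov, dmr.start, dmr.end, j, dmr))
            if cands:
                n_overlapping += 1
                best = min(cands)[4]
                combos[f"{dhr.direction}_{best.direction}"] += 1
        assert res["n_overlapping"] == n_overlapping
        assert res["combinations"] == combos


class TestTissueOverlap:
    def test_gene_mode_with_directions(self):
        sv = [deg(f"g{i}", "up" if i % 2 else "down") for i in range(10)]
        ut = [deg(f"g{i}", "up") for i in range(5, 15)]
        res = tissue_overlap(ut, sv, mode="genes")
        assert res["n_common"] == 5
        assert res["pct_of_a"] == percent(5, 10)
        assert res["n_same_direction"] == sum(1 for i in range(5, 10) if i % 2)

    def test_identical_sets(self):
        lst = [deg(f"g{i}") for i in range(8)]
        res = tissue_overlap(lst, list(lst), mode="genes")
        assert res["pct_of_a"] == res["pct_of_b"] == 100
        assert res["n_same_direction"] == 8

    def test_region_mode_by_coordinate(self, region_factory):
        a = [region_factory("chr1", 0, 1_000, "gain"),
             region_factory("chr1", 10_000, 11_000, "loss")]
        b = [region_factory("chr1", 500, 1_500, "gain"),
             region_factory("chr2", 0, 1_000, "loss")]
        res = tissue_overlap(a, b, mode="regions")
        assert res["n_common_a"] == 1 and res["n_common_b"] == 1
        assert res["n_same_direction"] == 1
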