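"""Windowed differential-region calling against independent oracles."""
import numpy as np
import pytest
from scipy import stats

from epiconcord.core import BinnedTrack, Genome
from epiconcord.diffregions import (
    call_differential_windows,
    merge_windows,
    region_overlap,
    rpm_normalize,
    window_counts,
    window_test_pvalue,
)


def track_from(genome, arrays, bin_width=50, library_size=None):
    counts = {c: np.asarray(a, dtype=np.int64) for c, a in arrays.items()}
    if library_size is None:
        return BinnedTrack.from_counts(genome, bin_width, counts)
    return BinnedTrack(genome, bin_width, counts, library_size)


class TestRPM:
    def test_definition_at_unit_library(self):
        g = Genome(("chr1",), (100,))
        t = track_from(g, {"chr1": [5, 0]}, library_size=1_000_000)
        rpm = rpm_normalize(t)
        assert rpm["chr1"].tolist() == [5.0, 0.0]

    def test_conservation_identity(self, rng):
        g = Genome(("chr1", "chr2"), (100_000, 50_000))
        t = track_from(g, {c: rng.poisson(2, g.n_bins(c, 50)) for c in g.names})
        rpm = rpm_normalize(t)
        total = sum(r.sum() for r in rpm.values()) * t.library_size / 1e6
        assert total == pytest.approx(t.total_counts(), rel=1e-12)

    def test_zero_library_rejected(self):
        g = Genome(("chr1",), (100,))
        with pytest.raises(ValueError):
            rpm_normalize(track_from(g, {"chr1": [0, 0]}))


class TestWindowCalling:
    def test_identical_tracks_yield_nothing(self, rng):
        g = Genome(("chr1",), (100_000,))
        counts = rng.poisson(3, g.n_bins("chr1", 50))
        t = track_from(g, {"chr1": counts})
        assert call_differential_windows(t, t) == []

    def test_extreme_window_is_reported_gain(self):
        g = Genome(("chr1",), (500,))
        a = track_from(g, {"chr1": [0] * 10}, library_size=1_000_000)
        b = track_from(g, {"chr1": [4] * 10}, library_size=1_000_000)
        (w,) = call_differential_windows(a, b)
        assert w.direction == "gain"
        assert w.fold > 2 and w.p_value < 0.01
        assert (w.interval.start, w.interval.end) == (0, 500)

    def test_mismatched_tiling_rejected(self):
        g = Genome(("chr1",), (1_000,))
        a = track_from(g, {"chr1": [1] * 20}, bin_width=50)
        b = track_from(Genome(("chr1",), (1_000,)), {"chr1": [1] * 10},
                       bin_width=100)
        with pytest.raises(ValueError):
            call_differential_windows(a, b)

    def test_matches_exact_binomial_oracle_bit_for_bit(self, rng):
        """Significant set identical to a brute-force scipy.stats.binomtest
        sweep over every window, including unequal library sizes."""
        g = Genome(("chr1",), (500_000,))  # 1,000 windows
        ca = rng.poisson(3.0, g.n_bins("chr1", 50))
        cb = rng.poisson(3.6, g.n_bins("chr1", 50))
        a, b = track_from(g, {"chr1": ca}), track_from(g, {"chr1": cb})
        called = {(w.interval.start, w.direction, w.p_value)
                  for w in call_differential_windows(a, b)}

        # independent oracle: per-window exact test + RPM fold filter
        wa = window_counts(a, 500)["chr1"]
        wb = window_counts(b, 500)["chr1"]
        la, lb = a.library_size, b.library_size
        expected = set()
        for i, (ka, kb) in enumerate(zip(wa, wb)):
            n = int(ka + kb)
            p = stats.binomtest(int(kb), n, lb / (la + lb)).pvalue if n else 1.0
            ra, rb = ka * 1e6 / la, kb * 1e6 / lb
            fold = (max(ra, rb) + 0.5) / (min(ra, rb) + 0.5)
            if fold >= 2 and p <= 0.01:
                expected.add((i * 500, "gain" if rb > ra else "loss", p))
        assert {(s, d) for s, d, _ in called} == {(s, d) for s, d, _ in expected}
        for (s, d, p), (s2, d2, p2) in zip(sorted(called), sorted(expected)):
            assert p == pytest.approx(p2, rel=1e-9)

    def test_swapping_tracks_swaps_direction_and_keeps_pvalues(self, rng):
        g = Genome(("chr1",), (200_000,))
        ca = rng.poisson(4, g.n_bins("chr1", 50))
        cb = rng.poisson(5, g.n_bins("chr1", 50))
        a, b = track_from(g, {"chr1": ca}), track_from(g, {"chr1": cb})
        fwd = call_differential_windows(a, b)
        rev = call_differential_windows(b, a)
        assert len(fwd) == len(rev) > 0
        flip = {"gain": "loss", "loss": "gain"}
        for wf, wr in zip(sorted(fwd, key=lambda w: w.interval.start),
                          sorted(rev, key=lambda w: w.interval.start)):
            assert wr.direction == flip[wf.direction]
            assert wr.p_value == wf.p_value  # exact, not approximate

    def test_null_significant_fraction_bounded(self):
        """10,000 null windows: significant fraction <= 0.01 + 3*SE."""
        g = Genome(("chr1",), (5_000_000,))
        n_windows, n_seeds = 10_000, 3
        se = np.sqrt(0.01 * 0.99 / n_windows)
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            a = track_from(g, {"chr1": r.poisson(8, g.n_bins("chr1", 50))})
            b = track_from(g, {"chr1": r.poisson(8, g.n_bins("chr1", 50))})
            frac = len(call_differential_windows(a, b)) / n_windows
            assert frac <= 0.01 + 3 * se


class TestPvalueFunction:
    @pytest.mark.parametrize("ka,kb,la,lb", [
        (0, 40, 1000, 1000), (7, 9, 1000, 1000), (12, 3, 500, 1500),
        (0, 0, 100, 100), (25, 25, 1000, 3000),
    ])
    def test_agrees_with_scipy_binomtest(self, ka, kb, la, lb):
        n = ka + kb
        expected = stats.binomtest(kb, n, lb / (la + lb)).pvalue if n else 1.0
        assert window_test_pvalue(ka, kb, la, lb) == pytest.approx(expected, rel=1e-9)


class TestMergeWindows:
    def test_adjacent_same_direction_merge(self):
        g = Genome(("chr1",), (2_000,))
        a = track_from(g, {"chr1": [0] * 40}, library_size=1_000_000)
        b = track_from(g, {"chr1": [4] * 20 + [0] * 20}, library_size=1_000_000)
        wins = call_differential_windows(a, b)
        assert len(wins) == 2
        (r,) = merge_windows(wins)
        assert (r.start, r.end, r.direction) == (0, 1000, "gain")
        assert r.p_value == min(w.p_value for w in wins)
        assert r.fold == max(w.fold for w in wins)

    def test_direction_partition(self):
        g = Genome(("chr1",), (1_000,))
        a = track_from(g, {"chr1": [0] * 10 + [4] * 10}, library_size=1_000_000)
        b = track_from(g, {"chr1": [4] * 10 + [0] * 10}, library_size=1_000_000)
        regions = merge_windows(call_differential_windows(a, b))
        assert len(regions) == 2
        assert {r.direction for r in regions} == {"gain", "loss"}

    def test_every_window_in_exactly_one_region_of_its_direction(self, rng):
        g = Genome(("chr1",), (1_000_000,))
        lam = np.full(g.n_bins("chr1", 50), 5.0)
        lam_b = lam.copy()
        for s in rng.choice(np.arange(0, len(lam) - 10, 10), 120, replace=False):
            lam_b[s: s + 10] *= 4
        a = track_from(g, {"chr1": rng.poisson(lam)})
        b = track_from(g, {"chr1": rng.poisson(lam_b)})
        wins = call_differential_windows(a, b)
        regions = merge_windows(wins)
        for w in wins:
            containing = [
                r for r in regions
                if r.direction == w.direction and r.chrom == w.interval.chrom
                and r.start <= w.interval.start and w.interval.end <= r.end
            ]
            assert len(containing) == 1
        # same-direction regions pairwise disjoint
        for d in ("gain", "loss"):
            rs = sorted([r for r in regions if r.direction == d],
                        key=lambda r: r.start)
            for r1, r2 in zip(rs, rs[1:]):
                assert r1.end <= r2.start


class TestRegionOverlap:
    def test_disjoint_and_identical(self, rng, genome, random_region_factory):
        regions = random_region_factory(rng, genome, 50)
        res = region_overlap(regions, regions)
        assert res["n_a_hit"] == res["n_b_hit"] == len(regions)
        assert region_overlap([], regions) == {"pairs": [], "n_a_hit": 0,
                                               "n_b_hit": 0}

    def test_matches_quadratic_bruteforce_oracle(self, rng, genome,
                                                 random_region_factory):
        a = random_region_factory(rng, genome, 200)
        b = [type(r)(r.interval.shifted(int(rng.integers(-3000, 3000))
                                        if r.start > 3000 else 0),
                     r.direction, r.fold, r.p_value, r.mark, r.comparison,
                     r.name)
             for r in random_region_factory(rng, genome, 200)]
        for min_ov in (1, 150):
            res = region_overlap(a, b, min_overlap_bp=min_ov)
            exp_pairs = set()
            for i, ra in enumerate(a):
                for j, rb in enumerate(b):
                    if ra.chrom != rb.chrom:
                        continue
                    ov = min(ra.end, rb.end) - max(ra.start, rb.start)
                    if ov >= min_ov:
                        exp_pairs.add((i, j, ov))
            assert set(res["pairs"]) == exp_pairs
            assert res["n_a_hit"] == len({i for i, _, _ in exp_pairs})
            assert res["n_b_hit"] == len({j for _, j, _ in exp_pairs})
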