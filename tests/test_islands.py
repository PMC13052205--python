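import numpy as np
import pytest

from divscan.formats import GeneRecord, GenomicInterval
from divscan.islands import (
    core_islands,
    empirical_top_fraction,
    genes_in_regions,
    merge_outlier_windows,
    regions_cover_subset,
)
from divscan.windows import Window


def mk_windows(coords, chrom="chr1"):
    return [Window(GenomicInterval(chrom, s, e), i) for i, (s, e) in enumerate(coords)]


class TestTopFraction:
    def test_top_one_percent_of_hundred(self):
        flagged, thr = empirical_top_fraction(np.arange(1, 101), 0.01)
        assert list(flagged) == [99]
        assert thr == 100

    def test_boundary_ties_all_included(self):
        vals = np.arange(1.0, 101.0)
        vals[98] = vals[99] = 99.5
        flagged, thr = empirical_top_fraction(vals, 0.01)
        assert sorted(flagged) == [98, 99]
        assert thr == 99.5

    def test_degenerate_all_equal_flags_everything(self, caplog):
        flagged, _ = empirical_top_fraction(np.ones(10), 0.2)
        assert len(flagged) == 10

    def test_nan_windows_excluded_before_ranking(self):
        vals = np.array([np.nan, 1.0, 5.0, np.nan, 3.0])
        flagged, thr = empirical_top_fraction(vals, 0.4)
        assert sorted(flagged) == [2, 4]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            empirical_top_fraction([1, 2], 0.0)
        with pytest.raises(ValueError):
            empirical_top_fraction([1, 2], 1.0)


class TestMerge:
    def test_overlap_and_distant_regions(self):
        w = mk_windows([(0, 50_000), (10_000, 60_000), (100_000, 150_000)])
        regions = merge_outlier_windows(w, [0, 1, 2], np.array([1.0, 2.0, 3.0]))
        spans = [(r.interval.start, r.interval.end) for r in regions]
        assert spans == [(0, 60_000), (100_000, 150_000)]
        assert regions[0].max_value == 2.0
        assert regions[0].mean_value == 1.5

    def test_gap_exactly_ten_kb_merges(self):
        w = mk_windows([(0, 50_000), (60_000, 110_000)])
        regions = merge_outlier_windows(w, [0, 1], np.zeros(2), max_gap=10_000)
        assert [(r.interval.start, r.interval.end) for r in regions] == [(0, 110_000)]
        # one bp wider gap stays separate
        w2 = mk_windows([(0, 50_000), (60_001, 110_001)])
        assert len(merge_outlier_windows(w2, [0, 1], np.zeros(2), max_gap=10_000)) == 2

    def test_single_window_is_its_own_region(self):
        w = mk_windows([(30_000, 80_000)])
        regions = merge_outlier_windows(w, [0], np.array([0.7]))
        assert [(r.interval.start, r.interval.end) for r in regions] == [(30_000, 80_000)]
        assert regions[0].interval.length == 50_000

    def test_empty_input(self):
        assert merge_outlier_windows([], np.array([], dtype=int), np.array([])) == []

    def test_window_order_invariance(self, rng):
        coords = [(int(s), int(s) + 50_000) for s in rng.integers(0, 10, 20) * 30_000]
        w = mk_windows(coords)
        vals = rng.random(20)
        flagged = rng.choice(20, size=8, replace=False)
        r1 = merge_outlier_windows(w, flagged, vals)
        r2 = merge_outlier_windows(w[::-1], flagged[::-1], vals)
        assert [(r.interval.start, r.interval.end) for r in r1] == [
            (r.interval.start, r.interval.end) for r in r2
        ]

    def test_against_exhaustive_fixpoint_oracle(self):
        """Merged output equals brute-force pairwise merging to a fixpoint."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = rng.integers(1, 12)
            starts = rng.integers(0, 40, size=n) * 10_000
            coords = [(int(s), int(s) + 50_000) for s in starts]
            gap = int(rng.choice([0, 5_000, 10_000, 20_000]))
            w = mk_windows(coords)
            flagged = np.arange(n)
            got = merge_outlier_windows(w, flagged, np.zeros(n), max_gap=gap)
            expected = _oracle_merge(coords, gap)
            assert [(r.interval.start, r.interval.end) for r in got] == expected


def _oracle_merge(coords, max_gap):
    """O(n^3) fixpoint merging: fuse any two intervals with gap <= max_gap."""
    items = [list(c) for c in coords]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                gap = max(a[0], b[0]) - min(a[1], b[1])
                if gap <= max_gap:
                    items[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((s, e) for s, e in items)


class TestCoreIslands:
    def test_window_level_intersection_then_merge(self):
        coords = [(i * 10_000, i * 10_000 + 50_000) for i in range(50)]
        w = mk_windows(coords)
        cores = core_islands([1, 2, 9], [2, 9, 40], w, max_gap=10_000)
        # windows 2 [20k,70k) and 9 [90k,140k): gap 20k > 10k -> 2 islands
        assert len(cores) == 2
        cores2 = core_islands([1, 2, 3], [2, 3, 40], w, max_gap=10_000)
        assert len(cores2) == 1  # windows 2,3 overlap -> one island
        assert (cores2[0].interval.start, cores2[0].interval.end) == (20_000, 80_000)

    def test_disjoint_flag_sets_yield_nothing(self):
        w = mk_windows([(0, 50_000), (10_000, 60_000)])
        assert core_islands([0], [1], w) == []

    def test_identical_flags_reduce_to_merged_regions(self):
        w = mk_windows([(0, 50_000), (100_000, 150_000), (200_000, 250_000)])
        flags = [0, 2]
        vals = np.array([1.0, 2.0, 3.0])
        cores = core_islands(flags, flags, w, values=vals)
        merged = merge_outlier_windows(w, np.array(flags), vals)
        assert [(r.interval.start, r.interval.end) for r in cores] == [
            (r.interval.start, r.interval.end) for r in merged
        ]

    def test_unknown_window_rejected(self):
        w = mk_windows([(0, 50_000)])
        with pytest.raises(ValueError, match="unknown windows"):
            core_islands([0], [5], w)

    def test_cover_subset_of_both_sources(self):
        rng = np.random.default_rng(5)
        coords = [(i * 10_000, i * 10_000 + 50_000) for i in range(100)]
        w = mk_windows(coords)
        vals = rng.random(100)
        f = rng.choice(100, 12, replace=False)
        d = rng.choice(100, 12, replace=False)
        cores = core_islands(f, d, w, values=vals)
        fr = merge_outlier_windows(w, f, vals, source="fst")
        dr = merge_outlier_windows(w, d, vals, source="dxy")
        assert regions_cover_subset(cores, fr)
        assert regions_cover_subset(cores, dr)


class TestGenesInRegions:
    GENES = [
        GeneRecord("g1", GenomicInterval("chr1", 100, 200)),
        GeneRecord("g2", GenomicInterval("chr1", 250, 400)),
        GeneRecord("g3", GenomicInterval("chr2", 0, 100)),
    ]

    def test_one_bp_overlap_suffices_and_halfopen_boundary_excludes(self):
        per, union = genes_in_regions(
            [GenomicInterval("chr1", 150, 300), GenomicInterval("chr1", 200, 250)], self.GENES
        )
        assert per[0] == ["g1", "g2"]
        assert per[1] == []  # [200,250) touches neither [100,200) nor [250,400)
        assert union == ["g1", "g2"]

    def test_shared_gene_counted_once_in_union(self):
        regions = [
            GenomicInterval("chr1", 100, 160),
            GenomicInterval("chr1", 160, 180),
            GenomicInterval("chr1", 180, 200),
        ]
        per, union = genes_in_regions(regions, self.GENES)
        assert all("g1" in lst for lst in per)
        assert union == ["g1"]

    def test_chromosome_separation(self):
        per, union = genes_in_regions([GenomicInterval("chr2", 50, 60)], self.GENES)
        assert union == ["g3"]
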