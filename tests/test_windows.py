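import numpy as np
import pytest

from divscan.formats import MISSING, GenotypeMatrix, PopulationMap
from divscan.windows import (
    individual_heterozygosity,
    make_windows,
    site_dxy,
    site_pi,
    summarize_windows,
    wc_fst,
    wc_site_components,
)
from .conftest import make_matrix


class TestMakeWindows:
    def test_sliding_enumeration(self):
        w = make_windows({"chr1": 100_000})
        assert len(w) == 10
        assert [x.interval.start for x in w] == list(range(0, 100_000, 10_000))
        assert (w[-1].interval.start, w[-1].interval.end) == (90_000, 100_000)

    def test_exact_multiple_and_short_chromosome(self):
        assert len(make_windows({"chr1": 50_000})) == 5
        w = make_windows({"chr1": 10})
        assert len(w) == 1
        assert (w[0].interval.start, w[0].interval.end) == (0, 10)

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            make_windows({"chr1": 1000}, size=100, step=200)


class TestSiteStatistics:
    def test_site_pi_pair_counting(self):
        assert site_pi(2, 4) == pytest.approx(4 / 6, abs=1e-12)
        assert site_pi(0, 4) == 0.0
        assert site_pi(1, 2) == 1.0

    def test_site_dxy_cross_population(self):
        assert site_dxy(1, 4, 3, 4) == pytest.approx(0.625, abs=1e-12)
        assert site_dxy(0, 4, 0, 6) == 0.0  # both fixed ref
        assert site_dxy(0, 4, 6, 6) == 1.0  # fixed difference

    def test_wc_fixed_difference_is_one(self):
        a, b, c = wc_site_components([[10, 0, 0], [0, 0, 10]])
        assert a / (a + b + c) == pytest.approx(1.0, abs=1e-12)

    def test_wc_identical_populations_nonpositive(self):
        a, b, c = wc_site_components([[3, 4, 3], [3, 4, 3]])
        assert a <= 0
        assert a / (a + b + c) <= 0

    def test_wc_uncallable_population_flagged(self):
        a, b, c = wc_site_components([[0, 0, 0], [2, 3, 1]])
        assert np.isnan(a) and np.isnan(b) and np.isnan(c)


def two_by_two_popmap():
    return PopulationMap({"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2"})


class TestSummarizeWindows:
    def test_dxy_with_invariant_denominator(self):
        """1 variant site (c1=1,n1=4; c2=3,n2=4) + 15 fully-called invariant sites
        in one window: Dxy = 10 / (16 * 16)."""
        calls = np.zeros((16, 4), dtype=np.int8)
        calls[0] = [0, 1, 1, 2]  # pop1 alt=1, pop2 alt=3
        is_variant = [True] + [False] * 15
        m = make_matrix(calls, is_variant=is_variant, samples=["a1", "a2", "b1", "b2"])
        w = make_windows({"chr1": 1601}, size=2000, step=2000)
        tab = summarize_windows(m, two_by_two_popmap(), w)
        assert tab.loc[0, "dxy"] == pytest.approx(10 / 256, abs=1e-12)
        assert tab.loc[0, "n_callable_pop1"] == 16

    def test_window_without_variants_has_zero_pi_and_undefined_fst(self):
        calls = np.zeros((5, 4), dtype=np.int8)
        m = make_matrix(calls, is_variant=[False] * 5, samples=["a1", "a2", "b1", "b2"])
        w = make_windows({"chr1": 600}, size=1000, step=1000)
        tab = summarize_windows(m, two_by_two_popmap(), w)
        assert tab.loc[0, "pi_pop1"] == 0.0
        assert tab.loc[0, "dxy"] == 0.0
        assert np.isnan(tab.loc[0, "fst"])

    def test_sample_order_invariance(self, rng):
        calls = rng.integers(-1, 3, size=(40, 4)).astype(np.int8)
        m = make_matrix(calls, samples=["a1", "a2", "b1", "b2"])
        perm = ["b2", "a1", "b1", "a2"]
        m2 = m.subset_samples(perm)
        w = make_windows({"chr1": 5000}, size=2000, step=1000)
        t1 = summarize_windows(m, two_by_two_popmap(), w)
        t2 = summarize_windows(m2, two_by_two_popmap(), w)
        for col in ("pi_pop1", "pi_pop2", "dxy", "fst"):
            np.testing.assert_allclose(t1[col], t2[col], rtol=1e-12)

    def test_dxy_symmetric_under_population_swap(self, rng):
        calls = rng.integers(-1, 3, size=(40, 4)).astype(np.int8)
        m = make_matrix(calls, samples=["a1", "a2", "b1", "b2"])
        w = make_windows({"chr1": 5000}, size=5000, step=5000)
        pm = two_by_two_popmap()
        swapped = PopulationMap({s: ("P2" if p == "P1" else "P1") for s, p in pm.assignments.items()})
        t1 = summarize_windows(m, pm, w)
        t2 = summarize_windows(m, swapped, w)
        np.testing.assert_allclose(t1["dxy"], t2["dxy"], rtol=1e-12)
        np.testing.assert_allclose(t1["fst"], t2["fst"], rtol=1e-12, equal_nan=True)
        # slot 1 holds the first-seen samples in both runs; only its label flips
        assert t2.attrs["populations"] == ("P2", "P1")
        np.testing.assert_allclose(t1["pi_pop1"], t2["pi_pop1"], rtol=1e-12)

    def test_popmap_with_three_populations_rejected(self, rng):
        calls = rng.integers(0, 3, size=(10, 3)).astype(np.int8)
        m = make_matrix(calls, samples=["a", "b", "c"])
        pm = PopulationMap({"a": "P1", "b": "P2", "c": "P3"})
        with pytest.raises(ValueError, match="2 populations"):
            summarize_windows(m, pm, make_windows({"chr1": 2000}, 2000, 2000))

    def test_panmictic_split_fst_near_zero_dxy_near_pi(self):
        """A random split of one panmictic pool: Fst ~ 0, Dxy ~ mean pi."""
        rng = np.random.default_rng(99)
        p = rng.uniform(0.1, 0.9, size=3000)
        calls = rng.binomial(2, p[:, None], size=(3000, 20)).astype(np.int8)
        samples = [f"s{i}" for i in range(20)]
        m = make_matrix(calls, pos=np.arange(1, 3001) * 10, samples=samples)
        order = rng.permutation(20)
        pm = PopulationMap({samples[i]: ("P1" if k < 10 else "P2") for k, i in enumerate(order)})
        w = make_windows({"chr1": 30_010}, size=30_010, step=30_010)
        tab = summarize_windows(m, pm, w)
        assert abs(wc_fst(m, pm)) < 0.01
        mean_pi = (tab.loc[0, "pi_pop1"] + tab.loc[0, "pi_pop2"]) / 2
        # per-site pi SE ~ sd/sqrt(S); tolerance 3 SE with sd < 0.35
        assert tab.loc[0, "dxy"] == pytest.approx(mean_pi, abs=3 * 0.35 / np.sqrt(3000))

    def test_mcar_masking_leaves_pi_and_dxy_unbiased(self):
        """The missing-data-aware denominators: masking 10% of genotypes MCAR
        moves genome pi/Dxy by far less than the estimate's own 3 SE."""
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, size=4000)
        calls = rng.binomial(2, p[:, None], size=(4000, 8)).astype(np.int8)
        samples = [f"s{i}" for i in range(8)]
        m = make_matrix(calls, pos=np.arange(1, 4001) * 10, samples=samples)
        pm = PopulationMap({s: ("P1" if i < 4 else "P2") for i, s in enumerate(samples)})
        w = make_windows({"chr1": 40_010}, size=40_010, step=40_010)
        base = summarize_windows(m, pm, w)
        masked_calls = calls.copy()
        masked_calls[rng.random(calls.shape) < 0.10] = MISSING
        m2 = make_matrix(masked_calls, pos=np.arange(1, 4001) * 10, samples=samples)
        masked = summarize_windows(m2, pm, w)
        se = 0.35 / np.sqrt(4000)  # upper bound on the per-site-mean SE
        for col in ("pi_pop1", "pi_pop2", "dxy"):
            assert abs(masked.loc[0, col] - base.loc[0, col]) < 3 * se


class TestHeterozygosity:
    def test_counting(self):
        m = make_matrix(np.array([[1], [1], [0], [2]]))
        het = individual_heterozygosity(m)
        assert het.loc[0, "het_rate"] == 0.5
        m2 = make_matrix(np.array([[0], [2], [2]]))
        assert individual_heterozygosity(m2).loc[0, "het_rate"] == 0.0

    def test_uncalled_sample_is_nan(self):
        m = make_matrix(np.array([[MISSING, 1], [MISSING, 0]]))
        het = individual_heterozygosity(m)
        assert np.isnan(het.loc[0, "het_rate"])
        assert het.loc[1, "het_rate"] == 0.5

    def test_hardy_weinberg_expectation(self):
        rng = np.random.default_rng(123)
        calls = rng.binomial(2, 0.5, size=(10_000, 1)).astype(np.int8)
        het = individual_heterozygosity(make_matrix(calls))
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert het.loc[0, "het_rate"] == pytest.approx(0.5, abs=3 * se)
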