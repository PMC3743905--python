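"""Shuffle validity, empirical-p arithmetic, the proximity/overlap
permutation tests and the rank-sum comparison."""

import numpy as np
import pytest
from scipy import stats

from conftest import exact_mannwhitney_p
from lncforge.genome_model import AnnotationSet, GenomicInterval, IntervalIndex
from lncforge.permutation import (
    IntergenicShuffler,
    IntronicShuffler,
    PlacementError,
    empirical_p,
    imprinted_proximity_test,
    rank_sum_compare,
    shuffle_intergenic,
    shuffle_intronic,
    unspliced_est_overlap_test,
)


class TestIntergenicShuffler:
    def test_degenerate_full_length_placement(self):
        sh = IntergenicShuffler({"chr1": 1000}, [])
        (iv,) = sh.shuffle([1000], np.random.default_rng(0))
        assert (iv.start, iv.end) == (0, 1000)

    def test_single_gap_exactly_fitting_is_forced(self):
        excl = [GenomicInterval("chr1", 0, 400), GenomicInterval("chr1", 600, 1000)]
        sh = IntergenicShuffler({"chr1": 1000}, excl)
        for seed in range(5):
            (iv,) = sh.shuffle([200], np.random.default_rng(seed))
            assert (iv.start, iv.end) == (400, 600)

    def test_no_placement_errors_with_transcript_name(self):
        excl = [GenomicInterval("chr1", 0, 900)]
        sh = IntergenicShuffler({"chr1": 1000}, excl)
        with pytest.raises(PlacementError, match="big"):
            sh.shuffle([500], np.random.default_rng(0), names=["big"])

    def test_placements_avoid_exclusions_and_keep_length(self):
        rng = np.random.default_rng(1)
        excl = [GenomicInterval("chr1", s, s + 300) for s in range(0, 50_000, 1_000)]
        idx = IntervalIndex(excl)
        sh = IntergenicShuffler({"chr1": 50_000, "chr2": 20_000}, excl)
        placed = sh.shuffle([1000] * 200 + [137] * 100, rng)
        for iv in placed:
            assert idx.overlap_length(iv.chrom, [(iv.start, iv.end)]) == 0
            assert iv.length in (1000, 137)

    def test_uniform_over_valid_starts(self):
        # two gaps with valid-start counts 1 and 9 for length 2
        excl = [GenomicInterval("chr1", 2, 10), GenomicInterval("chr1", 20, 30)]
        sh = IntergenicShuffler({"chr1": 30}, excl)  # gaps [0,2) and [10,20)
        rng = np.random.default_rng(5)
        ci, starts = sh.sample_placements(2, 20_000, rng)
        frac_first = float(np.mean(starts == 0))
        ci_low, ci_high = stats.binom.interval(0.999, 20_000, 1 / 10)
        assert ci_low <= frac_first * 20_000 <= ci_high

    def test_deterministic_under_seed(self):
        sh = IntergenicShuffler({"chr1": 100_000}, [])
        a = sh.shuffle([500] * 20, np.random.default_rng(9))
        b = sh.shuffle([500] * 20, np.random.default_rng(9))
        assert [(x.chrom, x.start) for x in a] == [(x.chrom, x.start) for x in b]


class TestIntronicShuffler:
    def test_forced_single_intron(self):
        sh = IntronicShuffler([GenomicInterval("chr1", 100, 300)])
        (iv,) = sh.shuffle([200], np.random.default_rng(0))
        assert (iv.start, iv.end) == (100, 300)

    def test_weighted_by_eligible_starts(self):
        introns = [
            GenomicInterval("chr1", 0, 100),     # 1 eligible start for len 100
            GenomicInterval("chr1", 500, 608),   # 9 eligible starts
        ]
        sh = IntronicShuffler(introns)
        rng = np.random.default_rng(2)
        _, starts = sh.sample_placements(100, 10_000, rng)
        n_first = int(np.sum(starts == 0))
        lo, hi = stats.binom.interval(0.999, 10_000, 1 / 10)
        assert lo <= n_first <= hi

    def test_containment(self):
        introns = [GenomicInterval("chr1", i * 1000, i * 1000 + 400) for i in range(20)]
        sh = IntronicShuffler(introns)
        placed = sh.shuffle([150] * 200, np.random.default_rng(3))
        for iv in placed:
            assert any(
                intr.start <= iv.start and iv.end <= intr.end for intr in introns
            )

    def test_no_eligible_intron_errors(self):
        sh = IntronicShuffler([GenomicInterval("chr1", 0, 100)])
        with pytest.raises(PlacementError):
            sh.shuffle([200], np.random.default_rng(0))


class TestEmpiricalP:
    def test_extremes_and_count(self):
        permuted = np.arange(1, 101)
        assert empirical_p(1000, permuted) == 0.0
        assert empirical_p(0, permuted) == 1.0
        permuted = np.arange(1, 10_001)
        assert empirical_p(9996, permuted) == 5 / 10_000

    def test_le_direction_and_add_one(self):
        permuted = np.arange(1, 101)
        assert empirical_p(1, permuted, "le") == 1 / 100
        assert empirical_p(1000, permuted, add_one=True) == 1 / 101

    def test_p_zero_reported_as_less_than(self):
        from lncforge.permutation import PermutationResult

        res = PermutationResult("s", 1.0, np.zeros(100), 0.0, 100, 0, "intergenic")
        assert res.p_text() == "< 0.01"


class TestProximityTest:
    def _inputs(self):
        chrom_sizes = {"chr1": 2_000_000}
        excl = [GenomicInterval("chr1", s, s + 10_000) for s in range(0, 2_000_000, 200_000)]
        loci = [GenomicInterval("chr1", 500_000, 510_000)]
        return chrom_sizes, excl, loci

    def test_extreme_enrichment_gives_zero_p(self):
        chrom_sizes, excl, loci = self._inputs()
        # observed loci all on top of the imprinted locus; exclusions leave
        # plenty of far-away placements, so permutations rarely all hit
        lnc = [GenomicInterval("chr1", 511_000, 511_600, name=f"l{i}") for i in range(10)]
        sh = IntergenicShuffler(chrom_sizes, excl)
        res = imprinted_proximity_test(lnc, loci, sh, n_perm=200, seed=0)
        assert res.observed == 1.0
        assert res.empirical_p < 0.05

    def test_deduplication_and_empty_loci(self):
        chrom_sizes, excl, loci = self._inputs()
        sh = IntergenicShuffler(chrom_sizes, excl)
        lnc = [GenomicInterval("chr1", 511_000, 511_600)]
        r1 = imprinted_proximity_test(lnc, loci, sh, n_perm=50, seed=1)
        r2 = imprinted_proximity_test(lnc, loci * 3, sh, n_perm=50, seed=1)
        assert r1.observed == r2.observed
        assert np.array_equal(r1.permuted, r2.permuted)
        with pytest.raises(ValueError):
            imprinted_proximity_test(lnc, [], sh, n_perm=10, seed=0)

    def test_proximity_boundary_inclusive_at_max_dist(self):
        loci = [GenomicInterval("chr1", 0, 1000)]
        sh = IntergenicShuffler({"chr1": 1_000_000}, [])
        at = [GenomicInterval("chr1", 1_100, 1_200)]  # distance 100
        res = imprinted_proximity_test(at, loci, sh, max_dist=100, n_perm=10, seed=0)
        assert res.observed == 1.0
        beyond = [GenomicInterval("chr1", 1_101, 1_201)]  # distance 101
        res = imprinted_proximity_test(beyond, loci, sh, max_dist=100, n_perm=10, seed=0)
        assert res.observed == 0.0

    def test_same_seed_identical_result(self):
        chrom_sizes, excl, loci = self._inputs()
        sh = IntergenicShuffler(chrom_sizes, excl)
        lnc = [GenomicInterval("chr1", 700_000, 700_600)]
        r1 = imprinted_proximity_test(lnc, loci, sh, n_perm=100, seed=11)
        r2 = imprinted_proximity_test(lnc, loci, sh, n_perm=100, seed=11)
        assert np.array_equal(r1.permuted, r2.permuted)
        assert r1.empirical_p == r2.empirical_p


class TestUnsplicedEstTest:
    def test_saturated_track_gives_p_one(self):
        sh = IntergenicShuffler({"chr1": 100_000}, [])
        ests = AnnotationSet("u", [GenomicInterval("chr1", 0, 100_000)])
        lnc = [GenomicInterval("chr1", 5_000, 5_600)]
        res = unspliced_est_overlap_test(lnc, ests, sh, n_perm=50, seed=0)
        assert res.observed == 1.0
        assert res.empirical_p == 1.0

    def test_zero_ests_observed_zero(self):
        sh = IntergenicShuffler({"chr1": 100_000}, [])
        lnc = [GenomicInterval("chr1", 5_000, 5_600)]
        res = unspliced_est_overlap_test(lnc, AnnotationSet("u", []), sh,
                                         n_perm=50, seed=0)
        assert res.observed == 0.0
        assert res.empirical_p == 1.0


class TestRankSumCompare:
    def test_exact_small_sample(self):
        u, p = rank_sum_compare([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_p_near_one(self):
        x = [1.0, 2.0, 5.5, 9.0]
        _, p = rank_sum_compare(x, list(x))
        assert p > 0.9

    def test_shift_decreases_p_monotonically(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 40)
        base = rng.normal(0, 1, 40)
        ps = [rank_sum_compare(x, base + shift)[1] for shift in (0.0, 1.0, 2.0, 4.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for n, m in [(2, 3), (4, 4), (5, 8), (8, 6)]:
            x = np.round(rng.normal(size=n), 3)
            y = np.round(rng.normal(size=m) + 0.5, 3)
            _, p = rank_sum_compare(x, y)
            assert p == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-9)
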