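"""Annotation stacking, track-support flags, CAGE distances, conservation
scoring, chromatin-mark rates and expression-matched sampling."""

import math

import numpy as np
import pytest

from conftest import brute_conservation_mean, random_intervals, random_transcript
from lncforge.characterize import (
    annotate_by_priority,
    cage_min_distances,
    chromatin_mark_rate,
    conservation_score,
    est_support,
    expression_matched_sample,
    nearest_coding_gene,
    repeat_overlap_flags,
)
from lncforge.genome_model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)


def transcript(tid, blocks, strand="+", chrom="chr1", expr=None):
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in blocks]
    return TranscriptModel(tid, chrom, strand, ivs, expression=expr or {"E14": 1.0})


def track(name, blocks, chrom="chr1", priority=None, scores=None):
    ivs = [
        GenomicInterval(chrom, s, e, score=None if scores is None else scores[i])
        for i, (s, e) in enumerate(blocks)
    ]
    return AnnotationSet(name, ivs, priority)


class TestAnnotateByPriority:
    def test_priority_wins_over_coverage(self):
        t = transcript("t", [(0, 1000)])
        est = track("EST", [(0, 100)], priority=4)       # 10% coverage
        transmap = track("TransMap", [(0, 900)], priority=1)  # 90% coverage
        labels = annotate_by_priority([t], [est, transmap])
        assert labels["t"] == "EST"

    def test_below_threshold_is_unannotated(self):
        t = transcript("t", [(0, 1000)])
        est = track("EST", [(0, 99)])  # 9.9%
        assert annotate_by_priority([t], [est])["t"] == "Unannotated"

    def test_no_overlap_is_unannotated(self):
        t = transcript("t", [(0, 1000)])
        assert annotate_by_priority([t], [track("EST", [(5000, 6000)])])["t"] == "Unannotated"

    def test_invalid_min_frac(self):
        with pytest.raises(ValueError):
            annotate_by_priority([], [], min_frac=0.0)

    def test_labels_match_per_base_fractions(self):
        rng = np.random.default_rng(17)
        sources = [
            track(name, [(iv.start, iv.end) for iv in random_intervals(rng, 15)])
            for name in ("EST", "mRNA", "NONCODE", "TransMap")
        ]
        ts = [random_transcript(rng, f"t{i}") for i in range(60)]
        labels = annotate_by_priority(ts, sources)
        from conftest import brute_overlap_length

        for t in ts:
            expected = "Unannotated"
            for src in sources:
                ov = brute_overlap_length(t.exon_blocks(), src.intervals, t.chrom)
                if ov >= 0.10 * t.exonic_length:
                    expected = src.name
                    break
            assert labels[t.id] == expected


class TestSupportFlags:
    def test_one_bp_overlap_supports(self):
        t = transcript("t", [(100, 200)])
        flags = est_support([t], track("s", [(199, 300)]), track("u", [(500, 600)]))
        assert bool(flags.loc["t", "spliced"]) is True
        assert bool(flags.loc["t", "unspliced"]) is False

    def test_repeat_fraction_strictly_greater(self):
        t = transcript("t", [(0, 1000)])
        at_5pct = repeat_overlap_flags([t], track("r", [(0, 50)]))
        above = repeat_overlap_flags([t], track("r", [(0, 51)]))
        assert not at_5pct["t"]
        assert above["t"]


class TestCageDistances:
    @pytest.mark.parametrize(
        "clusters,expected",
        [
            ([(90, 110)], 0.0),       # TSS inside cluster
            ([(200, 210)], 100.0),    # upstream-of-cluster gap
            ([(150, 160), (600, 610)], 50.0),  # nearest of two
        ],
    )
    def test_plus_strand_distances(self, clusters, expected):
        t = transcript("t", [(100, 400)], strand="+")
        d = cage_min_distances([t], track("cage", clusters))
        assert d["t"] == expected

    def test_minus_strand_uses_three_prime_end(self):
        t = transcript("t", [(100, 400)], strand="-")  # TSS at 399
        d = cage_min_distances([t], track("cage", [(300, 350)]))
        assert d["t"] == 50.0  # 399 - 349

    def test_no_cluster_on_chromosome_is_inf(self):
        t = transcript("t", [(100, 400)])
        d = cage_min_distances([t], track("cage", [(0, 10)], chrom="chr9"))
        assert math.isinf(d["t"])


class TestConservation:
    def test_no_overlap_scores_zero(self):
        t = transcript("t", [(0, 100)])
        assert conservation_score(t, track("c", [(500, 600)], scores=[0.9])) == 0.0

    def test_half_coverage_mean(self):
        t = transcript("t", [(0, 100)])
        els = track("c", [(0, 50)], scores=[0.8])
        assert conservation_score(t, els) == pytest.approx(0.40)

    def test_full_coverage_at_one(self):
        t = transcript("t", [(0, 100), (200, 300)])
        els = track("c", [(0, 100), (200, 300)], scores=[1.0, 1.0])
        assert conservation_score(t, els) == 1.0

    def test_mean_matches_per_base_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            t = random_transcript(rng, "t")
            # disjoint scored elements
            els = []
            pos = 0
            while pos < 9000:
                length = int(rng.integers(20, 200))
                if rng.random() < 0.4:
                    els.append(
                        GenomicInterval("chr1", pos, pos + length,
                                        score=round(float(rng.uniform(0, 1)), 3))
                    )
                pos += length + int(rng.integers(1, 100))
            anns = AnnotationSet("c", els)
            assert conservation_score(t, anns) == pytest.approx(
                brute_conservation_mean(t, els)
            )

    def test_invariant_to_element_splitting(self):
        t = transcript("t", [(0, 300)])
        whole = track("c", [(50, 250)], scores=[0.6])
        split = track("c", [(50, 150), (150, 250)], scores=[0.6, 0.6])
        for stat in ("mean", "median"):
            assert conservation_score(t, whole, stat) == pytest.approx(
                conservation_score(t, split, stat)
            )

    def test_median_majority_coverage(self):
        t = transcript("t", [(0, 100)])
        els = track("c", [(0, 60)], scores=[0.9])  # 60% of bases at 0.9
        assert conservation_score(t, els, "median") == 0.9
        sparse = track("c", [(0, 40)], scores=[0.9])  # 40% covered
        assert conservation_score(t, sparse, "median") == 0.0


class TestChromatinMarks:
    def test_window_boundary(self):
        t = transcript("t", [(10_000, 10_400)], strand="+")  # TSS 10000
        inside = {"m": track("m", [(14_990, 15_000)])}   # peak start at TSS+4990
        outside = {"m": track("m", [(15_001, 15_050)])}  # starts at TSS+5001
        assert chromatin_mark_rate([t], inside)["m"]["t"]
        assert not chromatin_mark_rate([t], outside)["m"]["t"]

    def test_window_monotonicity(self):
        rng = np.random.default_rng(44)
        ts = [random_transcript(rng, f"t{i}") for i in range(40)]
        peaks = {"m": track("m", [(iv.start, iv.end) for iv in random_intervals(rng, 10)])}
        prev = None
        for window in (500, 2000, 5000, 20_000):
            rate = chromatin_mark_rate(ts, peaks, window=window)["m"].mean()
            if prev is not None:
                assert rate >= prev
            prev = rate

    def test_body_fraction_criterion(self):
        t = transcript("t", [(0, 1000)])
        peaks = {"m": track("m", [(0, 499)])}
        assert not chromatin_mark_rate([t], peaks, criterion="body_fraction")["m"]["t"]
        peaks = {"m": track("m", [(0, 500)])}
        assert chromatin_mark_rate([t], peaks, criterion="body_fraction")["m"]["t"]

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            chromatin_mark_rate([], {}, window=0)


class TestNearestCodingGene:
    def _gene(self, gid, start, end, biotype="coding"):
        t = TranscriptModel(
            f"{gid}.1", "chr1", "+", [GenomicInterval("chr1", start, end, "+")],
            gene_id=gid,
        )
        return GeneModel(gid, biotype, [t])

    def test_overlap_and_minimum(self):
        t = transcript("t", [(1000, 1500)])
        overlapping = self._gene("gO", 1200, 2000)
        assert nearest_coding_gene(t, [overlapping])[1] == 0.0
        near = self._gene("gN", 1600, 1700)   # gap 100
        far = self._gene("gF", 1700, 1800)    # gap 200
        assert nearest_coding_gene(t, [far, near])[0] == "gN"

    def test_tie_break_is_deterministic(self):
        t = transcript("t", [(1000, 1500)])
        left = self._gene("gB", 800, 900)   # gap 100
        right = self._gene("gA", 1600, 1700)  # gap 100
        for _ in range(3):
            assert nearest_coding_gene(t, [right, left])[0] == "gB"  # smaller start

    def test_noncoding_ignored(self):
        t = transcript("t", [(1000, 1500)])
        nr = self._gene("gNR", 1600, 1700, biotype="noncoding")
        coding = self._gene("gC", 5000, 5100)
        assert nearest_coding_gene(t, [nr, coding])[0] == "gC"


class TestMatchedSampling:
    def _pool(self, rng, n, median):
        return [
            transcript(f"p{i}", [(i * 10, i * 10 + 5)],
                       expr={"E14": float(np.exp(np.log(median) + 0.5 * rng.standard_normal()))})
            for i in range(n)
        ]

    def test_identity_pool_reproduces_bin_masses(self):
        rng = np.random.default_rng(2)
        ref = self._pool(rng, 200, 3.0)
        sample = expression_matched_sample(ref, ref, seed=0)
        assert len(sample) == len(ref)
        ref_vals = np.log10([t.max_expression() + 1e-3 for t in ref])
        edges = np.quantile(ref_vals, np.linspace(0, 1, 11))
        edges[0], edges[-1] = -np.inf, np.inf
        ref_counts = np.histogram(ref_vals, edges)[0]
        sample_vals = np.log10([t.max_expression() + 1e-3 for t in sample])
        sample_counts = np.histogram(sample_vals, edges)[0]
        assert (ref_counts == sample_counts).all()

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        pool = self._pool(rng, 100, 3.0)
        ref = self._pool(rng, 80, 3.0)
        s1 = expression_matched_sample(pool, ref, seed=42)
        s2 = expression_matched_sample(pool, ref, seed=42)
        assert [t.id for t in s1] == [t.id for t in s2]

    def test_median_matching_across_seeds(self):
        rng = np.random.default_rng(4)
        pool = self._pool(rng, 300, 3.0)
        ref = self._pool(rng, 250, 3.0)
        ref_median = np.median(np.log10([t.max_expression() + 1e-3 for t in ref]))
        for seed in range(100):
            sample = expression_matched_sample(pool, ref, seed=seed)
            med = np.median(np.log10([t.max_expression() + 1e-3 for t in sample]))
            assert abs(med - ref_median) < 0.25

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            expression_matched_sample([], [transcript("t", [(0, 10)])])
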