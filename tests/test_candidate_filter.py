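"""Filter-cascade stages, the noise-threshold derivation, and cascade
invariants (monotonicity, idempotence, order-invariance)."""

import numpy as np
import pytest

from conftest import random_transcript
from lncforge.candidate_filter import (
    FilterAudit,
    FilterConfig,
    derive_noise_threshold,
    filter_class_code,
    filter_coding_potential,
    filter_coding_proximity,
    filter_expression,
    filter_min_length,
    filter_single_exon,
    merge_redundant,
    nearest_rank_percentile,
    run_filter_cascade,
)
from lncforge.genome_model import GeneModel, GenomicInterval, TranscriptModel


def make(tid, exon_blocks, strand="+", code="u", expr=None, cpc=-2.0, stages=None):
    ivs = [GenomicInterval("chr1", s, e, strand) for s, e in exon_blocks]
    return TranscriptModel(
        tid, "chr1", strand, ivs, class_code=code,
        expression=expr or {"E14": 1.0}, cpc_score=cpc,
        stage_presence=stages or {"E14"},
    )


class TestMergeRedundant:
    def test_identical_chains_collapse_with_union_of_stages(self):
        a = make("a", [(0, 100), (200, 300)], expr={"E14": 1.0}, stages={"E14"})
        b = make("b", [(0, 100), (200, 300)], expr={"E15": 2.0}, stages={"E15"})
        (merged,) = merge_redundant([a, b])
        assert merged.id == "a"
        assert merged.stage_presence == {"E14", "E15"}
        assert merged.expression == {"E14": 1.0, "E15": 2.0}

    def test_no_duplicates_is_identity(self):
        ts = [make("a", [(0, 100)]), make("b", [(500, 700)])]
        assert merge_redundant(ts) == ts

    def test_planted_duplicates_removed(self):
        rng = np.random.default_rng(0)
        originals = [random_transcript(rng, f"T{i:03d}") for i in range(80)]
        dups = [
            TranscriptModel(f"{t.id}_d", t.chrom, t.strand, list(t.exons))
            for t in originals[:20]
        ]
        merged = merge_redundant(originals + dups)
        # oracle: count distinct exon-chain keys
        keys = {t.exon_chain_key() for t in originals + dups}
        assert len(merged) == len(keys)

    def test_representative_id_is_order_independent(self):
        a = make("a", [(0, 100), (200, 300)])
        b = make("b", [(0, 100), (200, 300)])
        assert merge_redundant([b, a])[0].id == "a"


class TestLengthAndSingleExon:
    def test_length_boundary_is_strict(self):
        at = make("at", [(0, 200)], stages={"E14", "E15"})
        above = make("ab", [(0, 201)], stages={"E14", "E15"})
        kept = filter_min_length([at, above], 200)
        assert [t.id for t in kept] == ["ab"]

    def test_mixed_set_matches_recount(self):
        rng = np.random.default_rng(5)
        ts = [random_transcript(rng, f"T{i}") for i in range(10)]
        kept = filter_min_length(ts, 200)
        assert len(kept) == sum(1 for t in ts if t.exonic_length > 200)

    def test_single_exon_needs_two_stages(self):
        one = make("one", [(0, 400)], stages={"E14"})
        two = make("two", [(0, 400)], stages={"E14", "E17"})
        multi = make("multi", [(0, 200), (300, 500)], stages={"E15"})
        kept = filter_single_exon([one, two, multi], 2)
        assert {t.id for t in kept} == {"two", "multi"}


class TestNoiseThreshold:
    def test_mapping_rate_084_gives_16th_percentile(self):
        values = list(range(1, 101))
        assert derive_noise_threshold(values, 0.84) == 16

    def test_full_mapping_rate_keeps_minimum(self):
        assert derive_noise_threshold([5.0, 1.0, 3.0], 1.0) == 1.0

    def test_nearest_rank_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 10, size=37)
        for p in (0, 5, 16, 50, 95, 100):
            rank = max(1, int(np.ceil(p / 100 * len(values))))
            assert nearest_rank_percentile(values, p) == np.sort(values)[rank - 1]

    def test_empty_values_error(self):
        with pytest.raises(ValueError):
            derive_noise_threshold([], 0.84)


class TestExpressionClassCodeCpc:
    def test_expression_boundary_inclusive(self):
        low = make("low", [(0, 300)], expr={"E14": 0.29, "E15": 0.1})
        at = make("at", [(0, 300)], expr={"E14": 0.3})
        assert [t.id for t in filter_expression([low, at], 0.3)] == ["at"]

    def test_class_codes(self):
        u = make("u1", [(0, 300)], code="u")
        e = make("e1", [(0, 300)], code="e")
        assert [t.id for t in filter_class_code([u, e])] == ["u1"]
        assert filter_class_code([u, e], frozenset({"u", "e"})) == [u, e]

    def test_cpc_boundary_strict_and_missing_fails(self):
        kept_cases = [make("a", [(0, 300)], cpc=-1.5)]
        removed = [
            make("b", [(0, 300)], cpc=-1.0),
            make("c", [(0, 300)], cpc=2.0),
            make("d", [(0, 300)], cpc=None),
        ]
        assert filter_coding_potential(kept_cases + removed, -1.0) == kept_cases


class TestCodingProximity:
    def _gene(self, start, end):
        t = TranscriptModel(
            "g.1", "chr1", "+", [GenomicInterval("chr1", start, end, "+")], gene_id="g"
        )
        return GeneModel("g", "coding", [t])

    def test_gap_boundary(self):
        gene = self._gene(10_000, 12_000)
        near = make("near", [(12_999, 13_200), (13_400, 13_600)])  # gap 999
        at = make("at", [(13_000, 13_200), (13_400, 13_600)])      # gap 1000
        kept = filter_coding_proximity([near, at], [gene], 1000)
        assert [t.id for t in kept] == ["at"]

    def test_non_intergenic_passes_through(self):
        gene = self._gene(10_000, 12_000)
        close = make("close", [(12_010, 12_200)])
        kept = filter_coding_proximity(
            [close], [gene], 1000, intergenic_ids=set()
        )
        assert kept == [close]


class TestCascade:
    def test_empty_input(self):
        lnc, audit = run_filter_cascade([], [])
        assert lnc.all_transcripts() == []
        assert all(n_in == 0 and n_out == 0 for _, n_in, n_out in audit.rows)

    def test_default_config_values(self):
        cfg = FilterConfig()
        assert (cfg.min_length, cfg.expression_threshold, cfg.cpc_max,
                cfg.min_coding_distance) == (200, 0.3, -1.0, 1000)
        assert cfg.keep_class_codes == frozenset({"u", "i", "j", "x"})

    def test_config_requires_exactly_one_expression_rule(self):
        with pytest.raises(ValueError):
            FilterConfig(expression_threshold=0.3, mapping_rate=0.84)
        with pytest.raises(ValueError):
            FilterConfig(expression_threshold=None, mapping_rate=None)

    def test_audit_telescopes(self, cascade_result):
        _, audit = cascade_result
        frame = audit.to_frame()
        assert (frame["n_in"].iloc[1:].to_numpy()
                == frame["n_out"].iloc[:-1].to_numpy()).all()
        assert (frame["n_removed"] >= 0).all()

    def test_idempotent_on_own_output(self, default_fixture, cascade_result):
        lnc, _ = cascade_result
        survivors = lnc.all_transcripts()
        again, audit = run_filter_cascade(survivors, default_fixture.genes)
        assert {t.id for t in again.all_transcripts()} == {t.id for t in survivors}
        assert all(n_in == n_out for _, n_in, n_out in audit.rows)

    def test_input_order_invariance(self, default_fixture):
        rng = np.random.default_rng(9)
        shuffled = list(default_fixture.candidates)
        rng.shuffle(shuffled)
        lnc1, _ = run_filter_cascade(default_fixture.candidates, default_fixture.genes)
        lnc2, _ = run_filter_cascade(shuffled, default_fixture.genes)
        for cat in lnc1.categories:
            assert lnc1.ids(cat) == lnc2.ids(cat)

    def test_audit_rejects_non_telescoping_rows(self):
        audit = FilterAudit()
        audit.add("a", 10, 8)
        with pytest.raises(ValueError):
            audit.add("b", 9, 7)
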