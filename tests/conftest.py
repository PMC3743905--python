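"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's interval-index code
paths: overlap and classification are computed per base over explicit
Python sets, so they stay independent of the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from lncforge.candidate_filter import run_filter_cascade
from lncforge.genome_model import GenomicInterval, TranscriptModel
from lncforge.synthetic_data import FixtureConfig, generate_fixture


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def base_set(blocks):
    """All covered bases of a list of half-open (start, end) blocks."""
    out = set()
    for s, e in blocks:
        out.update(range(s, e))
    return out


def brute_overlap_length(a_blocks, b_intervals, chrom=None):
    """Per-base intersection size of exon blocks with an interval set."""
    a = base_set(a_blocks)
    b = set()
    for iv in b_intervals:
        if chrom is not None and iv.chrom != chrom:
            continue
        b.update(range(iv.start, iv.end))
    return len(a & b)


def brute_classify(t, genes):
    """Per-base reimplementation of the four-way classification rules."""
    span = set(range(t.span.start, t.span.end))
    gene_bases = {}
    for g in genes:
        if g.chrom != t.chrom:
            continue
        gene_bases[g.id] = set(range(g.span.start, g.span.end))
    if not any(span & b for b in gene_bases.values()):
        return "intergenic"
    for g in genes:
        if g.chrom != t.chrom or g.biotype != "coding":
            continue
        for intron in g.introns():
            if span <= set(range(intron.start, intron.end)):
                return "intronic"
    if t.strand in "+-":
        opposite = "-" if t.strand == "+" else "+"
        exon_bases = base_set(t.exon_blocks())
        for g in genes:
            if g.chrom != t.chrom:
                continue
            for tr in g.transcripts:
                if tr.strand != opposite:
                    continue
                for ex in tr.exons:
                    if exon_bases & set(range(ex.start, ex.end)):
                        return "cis_antisense"
    return "alt_spliced"


def brute_conservation_mean(t, elements):
    """Per-base mean conservation over the concatenated exonic bases."""
    scores = {}
    for iv in elements:
        if iv.chrom != t.chrom:
            continue
        for b in range(iv.start, iv.end):
            scores[b] = iv.score or 0.0
    bases = sorted(base_set(t.exon_blocks()))
    return sum(scores.get(b, 0.0) for b in bases) / len(bases)


def exact_mannwhitney_p(x, y):
    """Two-sided exact Mann-Whitney p by enumeration of group assignments."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) \
            + 0.5 * sum(1 for a in xs for b in ys if a == b)

    u_obs = u_of(x, y)
    mean_u = n * m / 2.0
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n + m) if i not in set(combo)]
        u = u_of(xs, ys)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def exact_hypergeom_tail(k, N, K, n):
    """Upper-tail P[X >= k] by exhaustive enumeration of drawn subsets."""
    from math import comb

    total = comb(N, n)
    hits = sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    )
    return hits / total


# ---------------------------------------------------------------------------
# random instance builders
# ---------------------------------------------------------------------------

def random_transcript(rng, tid, chrom="chr1", max_pos=9_000, n_exons=None):
    n_exons = n_exons or int(rng.integers(1, 4))
    pos = int(rng.integers(0, max_pos))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(20, 150))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(10, 120))
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel(
        tid, chrom, strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )


def random_intervals(rng, n, chrom="chr1", max_pos=10_000, max_len=200, scored=False):
    out = []
    for i in range(n):
        s = int(rng.integers(0, max_pos - max_len))
        e = s + int(rng.integers(1, max_len))
        score = round(float(rng.uniform(0, 1)), 3) if scored else None
        out.append(GenomicInterval(chrom, s, e, score=score))
    return out


# ---------------------------------------------------------------------------
# session fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_fixture():
    """The packaged default synthetic fixture (seed 1)."""
    return generate_fixture(FixtureConfig(), seed=1)


@pytest.fixture(scope="session")
def cascade_result(default_fixture):
    """Filter cascade output on the default fixture."""
    return run_filter_cascade(default_fixture.candidates, default_fixture.genes)
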