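"""Genomic classification of lncRNA candidates against reference gene models.

Candidates are partitioned into four mutually exclusive categories:

* ``intergenic`` — the span overlaps no reference gene span (coding or
  noncoding);
* ``intronic`` — the span is fully contained within a single intron of a
  protein-coding gene, in either orientation (introns are taken from the
  union-exon gene model);
* ``cis_antisense`` — at least one exon overlaps (>=1 bp) a reference exon
  on the opposite strand;
* ``alt_spliced`` — the residual: genic overlap that is neither
  intron-contained nor antisense-exonic (novel isoforms of known loci).

Precedence is exactly that order, which makes the categories a partition:
a candidate contained in an intron of a gene it is antisense to is
classified intronic, matching the mutual exclusion implicit in reported
per-category counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome_model import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    TranscriptModel,
)

log = logging.getLogger(__name__)

CATEGORIES = ("intergenic", "intronic", "cis_antisense", "alt_spliced")

__all__ = ["CATEGORIES", "LncRNASet", "GeneIndex", "classify_transcript", "classify_all"]


@dataclass
class LncRNASet:
    """Categorized lncRNA candidates plus classification side-products.

    ``antisense_partners`` records, per cis-antisense transcript, the gene
    ids whose exons it overlaps on the opposite strand; ``host_introns``
    records, per intronic transcript, the host gene id and intron.
    """

    categories: dict[str, list[TranscriptModel]] = field(
        default_factory=lambda: {c: [] for c in CATEGORIES}
    )
    antisense_partners: dict[str, list[str]] = field(default_factory=dict)
    host_introns: dict[str, tuple[str, GenomicInterval]] = field(default_factory=dict)

    def all_transcripts(self) -> list[TranscriptModel]:
        return [t for c in CATEGORIES for t in self.categories[c]]

    def ids(self, category: str) -> set[str]:
        return {t.id for t in self.categories[category]}

    def counts(self) -> dict[str, int]:
        return {c: len(self.categories[c]) for c in CATEGORIES}

    def category_of(self) -> dict[str, str]:
        return {t.id: c for c in CATEGORIES for t in self.categories[c]}


class GeneIndex:
    """Prebuilt interval indexes over a reference gene set.

    Spans of all genes (rule 1), union-exon introns of coding genes
    (rule 2) and stranded exons of all reference transcripts (rule 3).
    """

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self.span_index = IntervalIndex(g.span for g in self.genes)
        # genes whose span overlaps a query, for partner lookup
        self._spans_by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for g in self.genes:
            sp = g.span
            self._spans_by_chrom.setdefault(g.chrom, []).append((sp.start, sp.end, g))
        for v in self._spans_by_chrom.values():
            v.sort(key=lambda x: x[0])
        # coding-gene introns
        self._introns: dict[str, list[tuple[int, int, str]]] = {}
        for g in self.genes:
            if g.biotype != "coding":
                continue
            for intron in g.introns():
                self._introns.setdefault(g.chrom, []).append(
                    (intron.start, intron.end, g.id)
                )
        for v in self._introns.values():
            v.sort(key=lambda x: x[0])
        # stranded reference exons
        plus, minus = [], []
        self._exon_genes: dict[str, list[tuple[int, int, str, str]]] = {}
        for g in self.genes:
            for t in g.transcripts:
                for ex in t.exons:
                    (plus if t.strand == "+" else minus).append(ex)
                    self._exon_genes.setdefault(g.chrom, []).append(
                        (ex.start, ex.end, t.strand, g.id)
                    )
        self.exon_index = {"+": IntervalIndex(plus), "-": IntervalIndex(minus)}
        for v in self._exon_genes.values():
            v.sort(key=lambda x: x[0])

    def overlapping_genes(self, span: GenomicInterval) -> list[GeneModel]:
        out = []
        for s, e, g in self._spans_by_chrom.get(span.chrom, []):
            if s >= span.end:
                break
            if e > span.start:
                out.append(g)
        return out

    def containing_intron(
        self, span: GenomicInterval
    ) -> tuple[str, GenomicInterval] | None:
        for s, e, gid in self._introns.get(span.chrom, []):
            if s > span.start:
                break
            if s <= span.start and span.end <= e:
                return gid, GenomicInterval(span.chrom, s, e)
        return None

    def antisense_partner_genes(self, t: TranscriptModel) -> list[str]:
        opposite = "-" if t.strand == "+" else "+"
        partners = []
        for s, e, strand, gid in self._exon_genes.get(t.chrom, []):
            if strand != opposite:
                continue
            for ex in t.exons:
                if s < ex.end and ex.start < e:
                    partners.append(gid)
                    break
        return sorted(set(partners))


def classify_transcript(t: TranscriptModel, index: GeneIndex) -> str:
    """Assign one category to a transcript; see module docstring for rules."""
    span = t.span
    if not index.span_index.overlaps(span.chrom, span.start, span.end):
        return "intergenic"
    if index.containing_intron(span) is not None:
        return "intronic"
    if t.strand in ("+", "-"):
        opposite = "-" if t.strand == "+" else "+"
        exon_idx = index.exon_index[opposite]
        for ex in t.exons:
            if exon_idx.overlaps(ex.chrom, ex.start, ex.end):
                return "cis_antisense"
    else:
        log.debug("transcript %s is unstranded; cannot be cis-antisense", t.id)
    return "alt_spliced"


def classify_all(
    transcripts: Iterable[TranscriptModel],
    genes: Sequence[GeneModel] | GeneIndex,
) -> LncRNASet:
    """Classify every transcript; the result is a partition of the input."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    result = LncRNASet()
    for t in transcripts:
        cat = classify_transcript(t, index)
        result.categories[cat].append(t)
        if cat == "cis_antisense":
            result.antisense_partners[t.id] = index.antisense_partner_genes(t)
        elif cat == "intronic":
            host = index.containing_intron(t.span)
            if host is not None:
                result.host_introns[t.id] = host
    return result
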