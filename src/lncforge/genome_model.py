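"""Core genomic coordinate types plus GTF/BED readers and writers.

Every module in the package shares a single coordinate convention:
0-based, half-open ``[start, end)`` intervals on named chromosomes.
GTF (1-based, inclusive) is converted at the I/O boundary only.
Chromosome names are matched by exact string equality — no ``chr``
aliasing is attempted; a cross-chromosome distance is ``math.inf``.

Book-ended intervals (``a.end == b.start``) have distance 0, so every
"closer than X" filter downstream treats adjacency as proximal.
"""

from __future__ import annotations

import logging
import math
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "IntervalIndex",
    "read_gtf",
    "write_gtf",
    "read_gene_models",
    "read_bed",
    "write_bed",
    "read_transcript_table",
    "write_transcript_table",
    "apply_transcript_table",
    "overlap_length",
    "interval_distance",
    "merge_blocks",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF lines; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional strand/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between two spans; 0 if they overlap or are book-ended.

    Cross-chromosome pairs get ``math.inf``. Symmetric by construction.
    """
    if a.chrom != b.chrom:
        return math.inf
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def merge_blocks(blocks: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open blocks as a sorted, disjoint block list."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


@dataclass
class TranscriptModel:
    """One assembled transcript: an exon chain plus assembly metadata.

    ``expression`` maps stage name -> RPKM; ``stage_presence`` is the set of
    stages in which the model was assembled (which may be narrower than the
    stages with nonzero expression); ``class_code`` is the assembler's
    relation to reference annotation (u = novel intergenic, i = intronic,
    j = novel isoform, x = exonic antisense).
    """

    id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    class_code: str = "u"
    expression: dict[str, float] = field(default_factory=dict)
    cpc_score: float | None = None
    stage_presence: set[str] = field(default_factory=set)
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"transcript {self.id}: exon on {ex.chrom} != {self.chrom}")
            if ex.start < prev_end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
            prev_end = ex.end
        for v in self.expression.values():
            if v < 0:
                raise ValueError(f"transcript {self.id}: negative RPKM")

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand, name=self.id
        )

    def exon_blocks(self) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in self.exons]

    def tss(self) -> int:
        """Strand-aware 5' position. Unstranded models default to span start."""
        if self.strand == "+":
            return self.exons[0].start
        if self.strand == "-":
            return self.exons[-1].end - 1
        log.warning("transcript %s is unstranded; TSS defaults to span start", self.id)
        return self.exons[0].start

    def max_expression(self) -> float:
        return max(self.expression.values(), default=0.0)

    def exon_chain_key(self) -> tuple:
        """Hashable identity of the exon chain (used for redundancy merging)."""
        return (self.chrom, self.strand, tuple(self.exon_blocks()))


@dataclass
class GeneModel:
    """A gene locus: one or more transcripts sharing a gene id.

    ``biotype`` is "coding" (NM_-like) or "noncoding" (NR_-like). Introns are
    defined against the union of all transcript exons, so isoform-dependent
    ambiguity cannot leak into intron-containment tests.
    """

    id: str
    biotype: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"gene {self.id}: biotype {self.biotype!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.id}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(f"gene {self.id}: transcripts on multiple chromosomes")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        strands = {t.strand for t in self.transcripts}
        return strands.pop() if len(strands) == 1 else "."

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand, name=self.id)

    def exon_union(self) -> list[tuple[int, int]]:
        blocks: list[tuple[int, int]] = []
        for t in self.transcripts:
            blocks.extend(t.exon_blocks())
        return merge_blocks(blocks)

    def introns(self) -> list[GenomicInterval]:
        union = self.exon_union()
        out = []
        for (s1, e1), (s2, _) in zip(union, union[1:]):
            if s2 > e1:
                out.append(GenomicInterval(self.chrom, e1, s2, self.strand))
        return out


@dataclass
class AnnotationSet:
    """A named interval track (ESTs, repeats, CAGE clusters, peaks, ...)."""

    name: str
    intervals: list[GenomicInterval]
    priority: int | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


class IntervalIndex:
    """Per-chromosome sorted *merged* interval arrays for fast set queries.

    Because the blocks are merged into a disjoint union, overlap lengths
    against the index equal overlap against the union of the input set,
    which is the semantics every downstream "overlap" criterion uses.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, blocks in by_chrom.items():
            merged = merge_blocks(blocks)
            self._starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)

    @property
    def chroms(self) -> set[str]:
        return set(self._starts)

    def overlap_length(self, chrom: str, blocks: Sequence[tuple[int, int]]) -> int:
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        ends = self._ends[chrom]
        total = 0
        for s, e in blocks:
            lo = int(np.searchsorted(ends, s, side="right"))
            hi = int(np.searchsorted(starts, e, side="left"))
            for i in range(lo, hi):
                total += min(e, ends[i]) - max(s, starts[i])
        return total

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        ends = self._ends[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end

    def overlaps_many(self, chrom: str, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Vectorized span-overlap test against the merged union."""
        starts = self._starts.get(chrom)
        if starts is None:
            return np.zeros(len(start), dtype=bool)
        ends = self._ends[chrom]
        i = np.searchsorted(ends, start, side="right")
        ok = i < len(starts)
        res = np.zeros(len(start), dtype=bool)
        res[ok] = starts[np.minimum(i[ok], len(starts) - 1)] < end[ok]
        return res

    def distance(self, chrom: str, start: int, end: int) -> float:
        """Span distance to the nearest block; inf when the chrom is absent."""
        starts = self._starts.get(chrom)
        if starts is None:
            return math.inf
        ends = self._ends[chrom]
        i = int(np.searchsorted(starts, end, side="left"))
        best = math.inf
        if i < len(starts):
            best = min(best, starts[i] - end)
        if i > 0:
            best = min(best, max(0, start - ends[i - 1]))
        return max(0.0, best)

    def blocks(self, chrom: str) -> list[tuple[int, int]]:
        starts = self._starts.get(chrom)
        if starts is None:
            return []
        return list(zip(starts.tolist(), self._ends[chrom].tolist()))


def _as_blocks(a) -> tuple[str, list[tuple[int, int]]]:
    if isinstance(a, TranscriptModel):
        return a.chrom, a.exon_blocks()
    if isinstance(a, GenomicInterval):
        return a.chrom, [(a.start, a.end)]
    raise TypeError(f"cannot interpret {type(a)!r} as genomic blocks")


def overlap_length(a, b) -> int:
    """Total bases shared between ``a`` (interval or exon chain) and set ``b``.

    ``b`` may be an :class:`AnnotationSet`, an iterable of intervals, or a
    prebuilt :class:`IntervalIndex`. The result counts each base of ``a``
    at most once against the union of ``b``.
    """
    chrom, blocks = _as_blocks(a)
    if isinstance(b, IntervalIndex):
        idx = b
    elif isinstance(b, AnnotationSet):
        idx = IntervalIndex(b.intervals)
    else:
        idx = IntervalIndex(b)
    return idx.overlap_length(chrom, blocks)


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect; exon features with gene_id/transcript_id)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(s: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(s))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    GTF's 1-based inclusive coordinates are converted to internal 0-based
    half-open. Exons are grouped by ``transcript_id`` and sorted; an exon
    overlap within a transcript raises a validation error.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str | None]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-delimited fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            if tid is None:
                raise GtfParseError(f"{path}:{lineno}: missing transcript_id")
            exons.setdefault(tid, []).append(GenomicInterval(chrom, s, e, strand))
            meta.setdefault(tid, (chrom, strand, attr.get("gene_id")))
    out = []
    for tid, exs in exons.items():
        chrom, strand, gid = meta[tid]
        out.append(TranscriptModel(tid, chrom, strand, exs, gene_id=gid))
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "lncforge") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            gid = t.gene_id or t.id
            for ex in t.exons:
                attrs = f'gene_id "{gid}"; transcript_id "{t.id}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def read_gene_models(path: str | Path,
                     biotypes: Mapping[str, str] | None = None) -> list[GeneModel]:
    """Read a GTF and group transcripts into genes.

    Biotype comes from ``biotypes`` (gene id -> coding/noncoding) when given;
    otherwise an ``NR_``/``NONC`` id prefix marks a gene noncoding and
    anything else is treated as coding.
    """
    transcripts = read_gtf(path)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id or t.id, []).append(t)
    genes = []
    for gid, ts in by_gene.items():
        if biotypes is not None:
            biotype = biotypes.get(gid, "coding")
        else:
            biotype = "noncoding" if gid.startswith(("NR_", "NONC")) else "coding"
        genes.append(GeneModel(gid, biotype, ts))
    return genes


# ---------------------------------------------------------------------------
# BED I/O (BED3/BED6; native 0-based half-open kept as-is)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, name: str | None = None,
             priority: int | None = None) -> AnnotationSet:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            iv_name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, score, iv_name))
    return AnnotationSet(name or Path(path).stem, intervals, priority)


def write_bed(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in annotation.intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Transcript side-table (class code, CPC score, per-stage RPKM, stage presence)
# ---------------------------------------------------------------------------

def write_transcript_table(transcripts: Sequence[TranscriptModel],
                           path: str | Path) -> None:
    stages = sorted({s for t in transcripts for s in t.expression})
    rows = []
    for t in transcripts:
        row = {
            "transcript_id": t.id,
            "class_code": t.class_code,
            "cpc_score": t.cpc_score if t.cpc_score is not None else np.nan,
            "stage_presence": ",".join(sorted(t.stage_presence)),
        }
        for s in stages:
            row[f"rpkm_{s}"] = t.expression.get(s, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_transcript_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "class_code": str})


def apply_transcript_table(transcripts: Sequence[TranscriptModel],
                           table: pd.DataFrame) -> None:
    """Attach class codes, CPC scores and expression from the side table."""
    stage_cols = [c for c in table.columns if c.startswith("rpkm_")]
    by_id = table.set_index("transcript_id")
    for t in transcripts:
        if t.id not in by_id.index:
            continue
        row = by_id.loc[t.id]
        t.class_code = str(row["class_code"])
        cpc = row.get("cpc_score")
        t.cpc_score = None if pd.isna(cpc) else float(cpc)
        presence = row.get("stage_presence")
        if isinstance(presence, str) and presence:
            t.stage_presence = set(presence.split(","))
        t.expression = {c[len("rpkm_"):]: float(row[c]) for c in stage_cols}
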