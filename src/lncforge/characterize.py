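"""Multi-omic characterization of lncRNA candidates.

Annotation stacking by priority, EST/repeat/ribosome-footprint support,
CAGE 5'-completeness distances, exon-concatenated conservation scoring,
TSS-proximal chromatin-mark rates, nearest-coding-gene assignment and
expression-matched resampling.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    TranscriptModel,
    overlap_length,
)

log = logging.getLogger(__name__)

LOG_EPSILON = 1e-3  # RPKM pseudo-count admitting zeros in log transforms

__all__ = [
    "annotate_by_priority",
    "est_support",
    "repeat_overlap_flags",
    "ribosome_association",
    "cage_min_distances",
    "conservation_score",
    "chromatin_mark_rate",
    "nearest_coding_gene",
    "expression_matched_sample",
    "characterization_report",
]


def annotate_by_priority(
    transcripts: Sequence[TranscriptModel],
    annotation_sets: Sequence[AnnotationSet],
    min_frac: float = 0.10,
) -> dict[str, str]:
    """Label each transcript by the highest-priority annotation source that
    covers at least ``min_frac`` of its exonic length; else "Unannotated".

    ``annotation_sets`` are consulted in the given order unless they carry
    explicit ``priority`` ranks (higher rank wins).
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    ordered = list(annotation_sets)
    if all(s.priority is not None for s in ordered):
        ordered.sort(key=lambda s: -s.priority)
    indexes = [(s.name, IntervalIndex(s.intervals)) for s in ordered]
    labels = {}
    for t in transcripts:
        labels[t.id] = "Unannotated"
        needed = min_frac * t.exonic_length
        for name, idx in indexes:
            if idx.overlap_length(t.chrom, t.exon_blocks()) >= needed:
                labels[t.id] = name
                break
    return labels


def _overlap_flags(transcripts: Sequence[TranscriptModel],
                   track: AnnotationSet | IntervalIndex) -> pd.Series:
    idx = track if isinstance(track, IntervalIndex) else IntervalIndex(track.intervals)
    return pd.Series(
        {t.id: idx.overlap_length(t.chrom, t.exon_blocks()) > 0 for t in transcripts}
    )


def est_support(
    transcripts: Sequence[TranscriptModel],
    spliced_ests: AnnotationSet,
    unspliced_ests: AnnotationSet,
) -> pd.DataFrame:
    """Per-transcript EST support flags (>=1 bp exonic overlap).

    Returns a frame with boolean ``spliced``/``unspliced`` columns; support
    rates are the column means.
    """
    return pd.DataFrame(
        {
            "spliced": _overlap_flags(transcripts, spliced_ests),
            "unspliced": _overlap_flags(transcripts, unspliced_ests),
        }
    )


def repeat_overlap_flags(
    transcripts: Sequence[TranscriptModel],
    repeats: AnnotationSet,
    min_frac: float = 0.05,
) -> pd.Series:
    """Flag transcripts whose repeat overlap exceeds ``min_frac`` of their
    exonic length (strictly greater, so exactly 5% is not flagged)."""
    idx = IntervalIndex(repeats.intervals)
    return pd.Series(
        {
            t.id: idx.overlap_length(t.chrom, t.exon_blocks())
            > min_frac * t.exonic_length
            for t in transcripts
        }
    )


def ribosome_association(
    transcripts: Sequence[TranscriptModel],
    footprints: AnnotationSet,
) -> pd.Series:
    """Flag transcripts with >=1 bp exonic overlap with a ribosome footprint."""
    return _overlap_flags(transcripts, footprints)


def cage_min_distances(
    transcripts: Sequence[TranscriptModel],
    cage_clusters: AnnotationSet,
) -> pd.Series:
    """Shortest distance from each transcript's TSS to any CAGE cluster base.

    0 when the TSS lies inside a cluster; ``inf`` when no cluster shares the
    chromosome. CAGE matching is strand-agnostic.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in cage_clusters.intervals}:
        ivs = sorted(
            (iv for iv in cage_clusters.intervals if iv.chrom == chrom),
            key=lambda iv: iv.start,
        )
        by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    out = {}
    for t in transcripts:
        arrays = by_chrom.get(t.chrom)
        if arrays is None:
            out[t.id] = math.inf
            continue
        starts, ends = arrays
        tss = t.tss()
        i = int(np.searchsorted(starts, tss, side="right"))
        best = math.inf
        if i < len(starts):
            best = min(best, starts[i] - tss)
        if i > 0:
            # nearest base of the preceding cluster is ends[i-1]-1
            best = min(best, max(0, tss - (ends[i - 1] - 1)))
        out[t.id] = float(best)
    return pd.Series(out)


def conservation_score(
    t: TranscriptModel,
    elements: AnnotationSet,
    stat: str = "mean",
) -> float:
    """Conservation of the concatenated exonic bases of a transcript.

    Each exonic base takes the score of the covering element (elements are
    assumed disjoint, as conservation-element tracks are) and 0 where
    uncovered. ``stat`` "mean" averages over all exonic bases; "median" is
    the per-base weighted median.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    weights: list[tuple[float, int]] = []  # (score, n_bases)
    covered = 0
    for iv in elements.intervals:
        if iv.chrom != t.chrom:
            continue
        score = iv.score if iv.score is not None else 0.0
        for s, e in t.exon_blocks():
            ov = min(e, iv.end) - max(s, iv.start)
            if ov > 0:
                weights.append((float(score), ov))
                covered += ov
    n = t.exonic_length
    if covered < n:
        weights.append((0.0, n - covered))
    if stat == "mean":
        return sum(sc * w for sc, w in weights) / n
    weights.sort()
    half = n / 2.0
    acc = 0
    for sc, w in weights:
        acc += w
        if acc >= half:
            return sc
    return weights[-1][0]


def chromatin_mark_rate(
    transcripts: Sequence[TranscriptModel],
    peaks_by_mark: Mapping[str, AnnotationSet],
    window: int = 5000,
    criterion: str = "tss_window",
    body_min_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-mark flags for chromatin-peak association.

    ``tss_window`` (default): flagged iff any peak intersects
    ``[TSS - window, TSS + window)``. ``body_fraction``: flagged iff peak
    bases cover at least ``body_min_frac`` of the exonic length.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if criterion not in ("tss_window", "body_fraction"):
        raise ValueError(f"unknown criterion {criterion!r}")
    out = {}
    for mark, peaks in peaks_by_mark.items():
        idx = IntervalIndex(peaks.intervals)
        flags = {}
        for t in transcripts:
            if criterion == "tss_window":
                tss = t.tss()
                flags[t.id] = idx.overlaps(t.chrom, max(0, tss - window), tss + window)
            else:
                ov = idx.overlap_length(t.chrom, t.exon_blocks())
                flags[t.id] = ov >= body_min_frac * t.exonic_length
        out[mark] = pd.Series(flags)
    return pd.DataFrame(out)


def nearest_coding_gene(
    t: TranscriptModel,
    coding_genes: Sequence[GeneModel],
) -> tuple[str, float]:
    """Nearest coding gene by span-to-span distance.

    Ties are broken by smaller gene start, then lexicographic gene id, so
    the winner is deterministic across runs. Cross-chromosome-only cases
    return ``("", inf)``.
    """
    if not coding_genes:
        raise ValueError("need at least one coding gene")
    span = t.span
    best: tuple[float, int, str] | None = None
    for g in coding_genes:
        if g.biotype != "coding":
            continue
        gspan = g.span
        if gspan.chrom != span.chrom:
            continue
        d = max(0, max(span.start, gspan.start) - min(span.end, gspan.end))
        key = (d, gspan.start, g.id)
        if best is None or key < best:
            best = key
    if best is None:
        return "", math.inf
    return best[2], float(best[0])


def expression_matched_sample(
    pool: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    n: int | None = None,
    n_bins: int = 10,
    seed: int | np.random.Generator | None = None,
) -> list[TranscriptModel]:
    """Sample ``n`` pool members with replacement, matched to the reference
    log-expression distribution.

    The reference ``log10(max RPKM + 1e-3)`` values are cut into ``n_bins``
    quantile bins; per-bin sample counts follow the reference bin masses
    (largest-remainder apportionment), and members are drawn uniformly with
    replacement within each bin. An empty pool bin falls back to the
    nearest non-empty bin (logged).
    """
    if not pool:
        raise ValueError("empty pool")
    n = n if n is not None else len(reference)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def logexpr(ts):
        return np.log10(np.array([t.max_expression() for t in ts]) + LOG_EPSILON)

    ref_vals = logexpr(reference)
    pool_vals = logexpr(pool)
    edges = np.quantile(ref_vals, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    ref_bins = np.clip(np.searchsorted(edges, ref_vals, side="right") - 1, 0, n_bins - 1)
    pool_bins = np.clip(np.searchsorted(edges, pool_vals, side="right") - 1, 0, n_bins - 1)

    masses = np.bincount(ref_bins, minlength=n_bins) / len(ref_vals)
    raw = masses * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        frac_order = np.argsort(-(raw - counts), kind="stable")
        counts[frac_order[:remainder]] += 1

    members_by_bin = [np.flatnonzero(pool_bins == b) for b in range(n_bins)]
    non_empty = [b for b in range(n_bins) if len(members_by_bin[b]) > 0]
    sample: list[TranscriptModel] = []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        members = members_by_bin[b]
        if len(members) == 0:
            nearest = min(non_empty, key=lambda q: abs(q - b))
            log.warning("empty pool bin %d; falling back to bin %d", b, nearest)
            members = members_by_bin[nearest]
        picks = rng.integers(0, len(members), size=counts[b])
        sample.extend(pool[int(members[i])] for i in picks)
    return sample


def characterization_report(
    transcripts: Sequence[TranscriptModel],
    tracks: Mapping[str, AnnotationSet],
    coding_genes: Sequence[GeneModel] | None = None,
    annotation_order: Sequence[str] = ("spliced_est", "mrna", "noncode", "transmap"),
    peaks_by_mark: Mapping[str, AnnotationSet] | None = None,
) -> pd.DataFrame:
    """Assemble the per-transcript characterization table from named tracks.

    Recognized track names: ``spliced_est``, ``unspliced_est``, ``repeats``,
    ``ribosome``, ``cage``, ``conservation`` plus the stacking sources in
    ``annotation_order``; any absent track simply omits its columns.
    """
    df = pd.DataFrame(index=[t.id for t in transcripts])
    stack = [tracks[name] for name in annotation_order if name in tracks]
    if stack:
        df["annotation_label"] = pd.Series(annotate_by_priority(transcripts, stack))
    if "spliced_est" in tracks and "unspliced_est" in tracks:
        est = est_support(transcripts, tracks["spliced_est"], tracks["unspliced_est"])
        df["spliced_est_support"] = est["spliced"]
        df["unspliced_est_support"] = est["unspliced"]
    if "repeats" in tracks:
        df["repeat_flag"] = repeat_overlap_flags(transcripts, tracks["repeats"])
    if "ribosome" in tracks:
        df["ribosome_flag"] = ribosome_association(transcripts, tracks["ribosome"])
    if "cage" in tracks:
        df["cage_min_distance"] = cage_min_distances(transcripts, tracks["cage"])
    if "conservation" in tracks:
        df["conservation_score"] = pd.Series(
            {t.id: conservation_score(t, tracks["conservation"]) for t in transcripts}
        )
    if peaks_by_mark:
        marks = chromatin_mark_rate(transcripts, peaks_by_mark)
        for mark in marks.columns:
            df[f"mark_{mark}"] = marks[mark]
    if coding_genes is not None:
        nearest = {t.id: nearest_coding_gene(t, coding_genes) for t in transcripts}
        df["nearest_gene"] = pd.Series({k: v[0] for k, v in nearest.items()})
        df["nearest_gene_distance"] = pd.Series({k: v[1] for k, v in nearest.items()})
    return df
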