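"""The candidate-filter cascade: assembled transcripts -> lncRNA candidates.

The cascade applies, in order: redundancy merge, minimum exonic length
(>200 nt by default), the single-exon rule (single-exon models need
assembly support from at least two developmental stages), an expression
floor (max RPKM over stages >= 0.3, or a noise threshold derived from the
read-mapping rate), class-code selection ({u, i, j, x}), a coding-potential
ceiling (CPC score < -1), genomic classification, and finally removal of
intergenic candidates closer than 1,000 bp to a coding gene (which guards
against unannotated UTR fragments and promoter-divergent transcripts).

Every removed transcript is attributed to exactly one stage, and the
per-stage input/output counts are collected in a :class:`FilterAudit`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifier import GeneIndex, LncRNASet, classify_all
from .genome_model import GeneModel, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterAudit",
    "merge_redundant",
    "filter_min_length",
    "filter_single_exon",
    "derive_noise_threshold",
    "nearest_rank_percentile",
    "filter_expression",
    "filter_class_code",
    "filter_coding_potential",
    "filter_coding_proximity",
    "run_filter_cascade",
]

DEFAULT_KEEP_CODES = frozenset({"u", "i", "j", "x"})


@dataclass
class FilterConfig:
    """Thresholds driving the cascade. Defaults are the published cutoffs."""

    min_length: int = 200
    min_stage_support_single_exon: int = 2
    expression_threshold: float | None = 0.3
    mapping_rate: float | None = None
    keep_class_codes: frozenset[str] = DEFAULT_KEEP_CODES
    cpc_max: float = -1.0
    min_coding_distance: int = 1000

    def __post_init__(self) -> None:
        if (self.expression_threshold is None) == (self.mapping_rate is None):
            raise ValueError(
                "exactly one of expression_threshold / mapping_rate must be set"
            )
        if self.mapping_rate is not None and not (0 < self.mapping_rate <= 1):
            raise ValueError("mapping_rate must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        self.keep_class_codes = frozenset(self.keep_class_codes)


@dataclass
class FilterAudit:
    """Ordered per-stage (n_in, n_out) bookkeeping for the cascade."""

    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {stage}: n_out {n_out} > n_in {n_in}")
        if self.rows and self.rows[-1][2] != n_in:
            raise ValueError(f"stage {stage}: n_in does not telescope")
        self.rows.append((stage, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["stage", "n_in", "n_out"])
        df["n_removed"] = df["n_in"] - df["n_out"]
        return df

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {stage: (n_in, n_out) for stage, n_in, n_out in self.rows}


def merge_redundant(transcripts: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Collapse transcripts with identical exon chains to one representative.

    The representative is the lexicographically smallest id of the group
    (stable across runs and input orders); per-stage expression is
    max-merged and stage presence is unioned across the group.
    """
    groups: dict[tuple, list[TranscriptModel]] = {}
    order: list[tuple] = []
    for t in transcripts:
        key = t.exon_chain_key()
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(t)
    out = []
    for key in order:
        group = sorted(groups[key], key=lambda t: t.id)
        rep = group[0]
        if len(group) > 1:
            expression = dict(rep.expression)
            presence = set(rep.stage_presence)
            for other in group[1:]:
                for stage, v in other.expression.items():
                    expression[stage] = max(expression.get(stage, 0.0), v)
                presence |= other.stage_presence
            rep = replace(rep, expression=expression, stage_presence=presence)
        out.append(rep)
    return out


def filter_min_length(transcripts: Iterable[TranscriptModel],
                      min_length: int = 200) -> list[TranscriptModel]:
    """Keep transcripts with exonic length strictly greater than ``min_length``."""
    return [t for t in transcripts if t.exonic_length > min_length]


def filter_single_exon(transcripts: Iterable[TranscriptModel],
                       min_stage_support: int = 2) -> list[TranscriptModel]:
    """Drop single-exon models unless assembled in >= ``min_stage_support`` stages."""
    return [
        t for t in transcripts
        if t.n_exons > 1 or len(t.stage_presence) >= min_stage_support
    ]


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the value at rank ``ceil(p/100 * n)`` (min 1)."""
    vals = np.sort(np.asarray(values, dtype=float))
    if vals.size == 0:
        raise ValueError("empty value set")
    # tolerance guards ceil against float artifacts (e.g. 100*(1-0.84))
    rank = max(1, math.ceil(percentile / 100.0 * vals.size - 1e-9))
    return float(vals[min(rank, vals.size) - 1])


def derive_noise_threshold(expression_values: Sequence[float],
                           mapping_rate: float) -> float:
    """Expression noise floor from the average read-mapping rate.

    With a mapping rate m, the bottom ``100*(1-m)`` percent of the pooled
    expression signal is treated as noise, so the threshold is the
    nearest-rank percentile of the pooled values at ``100*(1-m)``
    (e.g. an 84% mapping rate puts the floor at the 16th percentile).
    """
    if not 0 < mapping_rate <= 1:
        raise ValueError("mapping_rate must be in (0, 1]")
    return nearest_rank_percentile(expression_values, 100.0 * (1.0 - mapping_rate))


def filter_expression(transcripts: Iterable[TranscriptModel],
                      threshold: float) -> list[TranscriptModel]:
    """Keep transcripts whose maximum RPKM over stages is >= ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [t for t in transcripts if t.max_expression() >= threshold]


def filter_class_code(transcripts: Iterable[TranscriptModel],
                      keep_codes: frozenset[str] = DEFAULT_KEEP_CODES
                      ) -> list[TranscriptModel]:
    out = []
    for t in transcripts:
        if t.class_code in keep_codes:
            out.append(t)
        elif t.class_code not in {"u", "i", "j", "x", "=", "c", "e", "o", "p", "s", "."}:
            log.warning("transcript %s: unknown class code %r removed", t.id, t.class_code)
    return out


def filter_coding_potential(transcripts: Iterable[TranscriptModel],
                            cpc_max: float = -1.0) -> list[TranscriptModel]:
    """Keep transcripts with CPC score strictly below ``cpc_max``.

    A missing score fails the filter (conservative).
    """
    return [t for t in transcripts if t.cpc_score is not None and t.cpc_score < cpc_max]


def filter_coding_proximity(transcripts: Iterable[TranscriptModel],
                            coding_genes: Sequence[GeneModel],
                            min_coding_distance: int = 1000,
                            intergenic_ids: set[str] | None = None
                            ) -> list[TranscriptModel]:
    """Remove intergenic transcripts closer than ``min_coding_distance`` bp
    to the nearest coding gene span. Non-intergenic transcripts pass through.

    ``intergenic_ids`` limits the rule's scope; when omitted every
    transcript is treated as subject to the rule.
    """
    from .genome_model import IntervalIndex

    coding = [g for g in coding_genes if g.biotype == "coding"]
    if not coding:
        log.warning("no coding genes supplied; coding-proximity filter is a no-op")
        return list(transcripts)
    index = IntervalIndex(g.span for g in coding)
    out = []
    for t in transcripts:
        if intergenic_ids is not None and t.id not in intergenic_ids:
            out.append(t)
            continue
        span = t.span
        if index.distance(span.chrom, span.start, span.end) >= min_coding_distance:
            out.append(t)
    return out


def run_filter_cascade(
    transcripts: Sequence[TranscriptModel],
    gene_models: Sequence[GeneModel],
    config: FilterConfig | None = None,
) -> tuple[LncRNASet, FilterAudit]:
    """Run the full cascade and classify the survivors.

    Returns the categorized survivor set and the per-stage audit. The
    expression threshold is either the configured RPKM floor or, when a
    mapping rate is configured instead, the noise percentile derived from
    the pooled nonzero expression values of the post-single-exon set.
    """
    config = config or FilterConfig()
    audit = FilterAudit()
    current = list(transcripts)

    merged = merge_redundant(current)
    audit.add("merge", len(current), len(merged))
    current = merged

    kept = filter_min_length(current, config.min_length)
    audit.add("min_length", len(current), len(kept))
    current = kept

    kept = filter_single_exon(current, config.min_stage_support_single_exon)
    audit.add("single_exon", len(current), len(kept))
    current = kept

    if config.expression_threshold is not None:
        threshold = config.expression_threshold
    else:
        pooled = [v for t in current for v in t.expression.values() if v > 0]
        threshold = derive_noise_threshold(pooled, config.mapping_rate)
        log.info("derived expression noise threshold: %.4g RPKM", threshold)
    kept = filter_expression(current, threshold)
    audit.add("expression", len(current), len(kept))
    current = kept

    kept = filter_class_code(current, config.keep_class_codes)
    audit.add("class_code", len(current), len(kept))
    current = kept

    kept = filter_coding_potential(current, config.cpc_max)
    audit.add("coding_potential", len(current), len(kept))
    current = kept

    index = GeneIndex(gene_models)
    classified = classify_all(current, index)
    intergenic_ids = classified.ids("intergenic")
    kept = filter_coding_proximity(
        current, gene_models, config.min_coding_distance, intergenic_ids
    )
    audit.add("coding_proximity", len(current), len(kept))

    final = classify_all(kept, index)
    return final, audit
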