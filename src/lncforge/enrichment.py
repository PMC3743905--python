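"""Gene-list construction for functional enrichment, plus a generic
hypergeometric term-enrichment test with Benjamini-Hochberg correction.

The three list builders mirror how candidate lncRNA categories are tied to
protein-coding genes: intergenic candidates contribute their nearest coding
gene when closer than 500 kb; intronic candidates contribute their host
gene unless the containing intron exceeds 100 kb; cis-antisense candidates
contribute their opposite-strand exon partners.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .characterize import nearest_coding_gene
from .classifier import LncRNASet
from .genome_model import GeneModel, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "closest_gene_list",
    "host_gene_list",
    "overlapping_gene_list",
    "term_enrichment",
]


def closest_gene_list(
    intergenic_lncrnas: Sequence[TranscriptModel],
    coding_genes: Sequence[GeneModel],
    max_dist: int = 500_000,
) -> list[str]:
    """Unique nearest-coding-gene ids at distance strictly below ``max_dist``.

    One gene per lncRNA; the result is deduplicated, input order preserved.
    """
    seen: dict[str, None] = {}
    for t in intergenic_lncrnas:
        gid, dist = nearest_coding_gene(t, coding_genes)
        if gid and dist < max_dist:
            seen.setdefault(gid, None)
    return list(seen)


def host_gene_list(
    intronic_lncrnas: Sequence[TranscriptModel],
    lnc_set: LncRNASet,
    max_intron: int = 100_000,
) -> list[str]:
    """Host gene ids of intronic lncRNAs whose containing intron is at most
    ``max_intron`` bp long (longer introns are discarded as uninformative).

    Raises if a transcript has no recorded host intron, which would mean
    the classification contract was breached upstream.
    """
    seen: dict[str, None] = {}
    for t in intronic_lncrnas:
        host = lnc_set.host_introns.get(t.id)
        if host is None:
            raise ValueError(f"transcript {t.id} has no recorded host intron")
        gid, intron = host
        if intron.length <= max_intron:
            seen.setdefault(gid, None)
    return list(seen)


def overlapping_gene_list(
    cis_antisense_lncrnas: Sequence[TranscriptModel],
    lnc_set: LncRNASet,
) -> list[str]:
    """Deduplicated opposite-strand partner gene ids of cis-antisense lncRNAs."""
    seen: dict[str, None] = {}
    for t in cis_antisense_lncrnas:
        for gid in lnc_set.antisense_partners.get(t.id, []):
            seen.setdefault(gid, None)
    return list(seen)


def term_enrichment(
    gene_list: Sequence[str],
    background: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each term in ``gene_list``.

    For a term with K members among N background genes, observing k hits in
    a list of n genes has p = P[X >= k], X ~ Hypergeom(N, K, n). P-values
    are BH-adjusted across the tested terms; terms with no background
    members are skipped. Raises if the gene list is not a subset of the
    background.
    """
    bg = set(background)
    genes = set(gene_list)
    offenders = sorted(genes - bg)
    if offenders:
        raise ValueError(f"gene list not within background: {offenders}")
    N, n = len(bg), len(genes)
    rows = []
    for term, members in term_map.items():
        members = set(members) & bg
        K = len(members)
        if K == 0:
            continue
        k = len(genes & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "adjusted_p"])
    df = pd.DataFrame(rows)
    df["adjusted_p"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["adjusted_p", "p", "term"], kind="stable").reset_index(drop=True)
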