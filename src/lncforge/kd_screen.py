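"""Knockdown perturbation calling from microarray profiles.

Probes are mapped onto lncRNA exon chains by genomic coordinates (>99%
of the probe's bases exonic by default). Per-probe up/down thresholds are
the nearest-rank 95th/5th percentiles of the control profiles, and a
knockdown target's regulated lncRNAs are those whose mapped probes exceed
the thresholds in every replicate ("both" rule; a replicate-mean rule is
available). A permutation null re-draws the mapped probe subset from the
whole array universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .candidate_filter import nearest_rank_percentile
from .genome_model import GenomicInterval, IntervalIndex, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "KDExperiment",
    "RegulationCall",
    "map_probes_to_lncrnas",
    "control_percentile_thresholds",
    "call_regulation",
    "regulator_summary",
]


@dataclass
class KDExperiment:
    """A knockdown screen: probes, control matrix and replicated KD profiles.

    ``controls`` is probes x control profiles; each entry of ``kd`` is a
    probes x replicates frame sharing the control probe index;
    ``target_type`` labels each target "protein" or "lncrna" (lncRNA
    knockdowns serve as negative controls).
    """

    probes: dict[str, GenomicInterval]
    controls: pd.DataFrame
    kd: dict[str, pd.DataFrame]
    target_type: dict[str, str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.controls.to_numpy()).all():
            raise ValueError("non-finite control values")
        for target, frame in self.kd.items():
            if not frame.index.equals(self.controls.index):
                raise ValueError(f"target {target}: probe universe mismatch")


@dataclass
class RegulationCall:
    """Up/down-regulated lncRNA sets for one knockdown target."""

    target: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError(f"target {self.target}: up/down sets overlap")

    @property
    def affected(self) -> int:
        return len(self.up) + len(self.down)


def map_probes_to_lncrnas(
    probes: Mapping[str, GenomicInterval],
    lncrnas: Sequence[TranscriptModel],
    min_frac: float = 0.99,
) -> dict[str, list[str]]:
    """Map probes onto lncRNAs requiring > ``min_frac`` of the probe's bases
    to fall in the lncRNA's exons. Probes hitting several lncRNAs map to
    all of them (flagged ambiguous in the log)."""
    indexes = [(t.id, t.chrom, IntervalIndex(t.exons)) for t in lncrnas]
    mapping: dict[str, list[str]] = {}
    for pid, probe in probes.items():
        hits = []
        for tid, chrom, idx in indexes:
            if chrom != probe.chrom:
                continue
            ov = idx.overlap_length(probe.chrom, [(probe.start, probe.end)])
            if ov > min_frac * probe.length:
                hits.append(tid)
        if hits:
            if len(hits) > 1:
                log.warning("probe %s maps ambiguously to %d lncRNAs", pid, len(hits))
            mapping[pid] = hits
    return mapping


def control_percentile_thresholds(
    controls: pd.DataFrame,
    lo: float = 5,
    hi: float = 95,
) -> pd.DataFrame:
    """Per-probe nearest-rank percentile thresholds across control profiles.

    Returns a frame indexed by probe with ``lo_value``, ``hi_value`` and a
    ``callable`` flag; a probe with lo == hi (constant controls) is
    excluded from calling.
    """
    if controls.shape[1] < 2:
        raise ValueError("need at least 2 control profiles")
    lo_vals, hi_vals = {}, {}
    for probe, row in controls.iterrows():
        vals = row.to_numpy(dtype=float)
        lo_vals[probe] = nearest_rank_percentile(vals, lo)
        hi_vals[probe] = nearest_rank_percentile(vals, hi)
    out = pd.DataFrame({"lo_value": lo_vals, "hi_value": hi_vals})
    out = out.loc[controls.index]
    out["callable"] = out["lo_value"] < out["hi_value"]
    n_uncallable = int((~out["callable"]).sum())
    if n_uncallable:
        log.warning("%d probes uncallable (constant control values)", n_uncallable)
    return out


def _probe_calls(
    profile: pd.DataFrame,
    thresholds: pd.DataFrame,
    replicate_rule: str,
) -> tuple[pd.Series, pd.Series]:
    """Boolean per-probe up/down calls for one target's replicate frame."""
    if profile.isna().any().any():
        raise ValueError("missing replicate values")
    values = profile.to_numpy(dtype=float)
    hi = thresholds["hi_value"].to_numpy()
    lo = thresholds["lo_value"].to_numpy()
    callable_ = thresholds["callable"].to_numpy()
    if replicate_rule == "both":
        up = (values > hi[:, None]).all(axis=1)
        down = (values < lo[:, None]).all(axis=1)
    elif replicate_rule == "mean":
        mean = values.mean(axis=1)
        up = mean > hi
        down = mean < lo
    else:
        raise ValueError(f"unknown replicate_rule {replicate_rule!r}")
    up &= callable_
    down &= callable_
    return (
        pd.Series(up, index=profile.index),
        pd.Series(down, index=profile.index),
    )


def call_regulation(
    kd_profiles: Mapping[str, pd.DataFrame],
    thresholds: pd.DataFrame,
    probe_map: Mapping[str, Sequence[str]],
    replicate_rule: str = "both",
) -> dict[str, RegulationCall]:
    """Per-target up/down lncRNA calls.

    A lncRNA is up-regulated for a target iff any of its mapped probes is
    called up (and none down — conflicting probes resolve to no call,
    logged); symmetrically for down.
    """
    lnc_probes: dict[str, list[str]] = {}
    for pid, tids in probe_map.items():
        for tid in tids:
            lnc_probes.setdefault(tid, []).append(pid)
    calls = {}
    for target, profile in kd_profiles.items():
        probe_up, probe_down = _probe_calls(
            profile.loc[thresholds.index], thresholds, replicate_rule
        )
        up, down = set(), set()
        for tid, pids in lnc_probes.items():
            any_up = any(probe_up.get(p, False) for p in pids)
            any_down = any(probe_down.get(p, False) for p in pids)
            if any_up and any_down:
                log.debug("target %s: conflicting probe calls for %s", target, tid)
                continue
            if any_up:
                up.add(tid)
            elif any_down:
                down.add(tid)
        calls[target] = RegulationCall(target, up, down)
    return calls


def regulator_summary(
    calls: Mapping[str, RegulationCall],
    target_type: Mapping[str, str],
    kd_profiles: Mapping[str, pd.DataFrame] | None = None,
    thresholds: pd.DataFrame | None = None,
    n_mapped: int | None = None,
    replicate_rule: str = "both",
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ranked per-target affected counts with an optional permutation null.

    The null re-draws ``n_mapped`` probes uniformly from the whole probe
    universe per permutation (one shared draw per permutation across
    targets) and counts called probes among them, giving a per-target
    empirical p for the observed affected count.
    """
    rows = []
    for target, call in calls.items():
        rows.append(
            {
                "target": target,
                "type": target_type.get(target, "unknown"),
                "n_up": len(call.up),
                "n_down": len(call.down),
                "affected": call.affected,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["affected", "target"], ascending=[False, True], kind="stable"
    )
    table["rank"] = np.arange(1, len(table) + 1)

    if kd_profiles is not None and thresholds is not None and n_mapped:
        rng = np.random.default_rng(seed)
        n_probes = len(thresholds)
        called = np.zeros((len(table), n_probes), dtype=bool)
        targets = table["target"].tolist()
        for i, target in enumerate(targets):
            up, down = _probe_calls(
                kd_profiles[target].loc[thresholds.index], thresholds, replicate_rule
            )
            called[i] = up.to_numpy() | down.to_numpy()
        null_counts = np.zeros((n_perm, len(targets)), dtype=np.int64)
        for j in range(n_perm):
            subset = rng.choice(n_probes, size=n_mapped, replace=False)
            null_counts[j] = called[:, subset].sum(axis=1)
        observed = table["affected"].to_numpy()
        exceed = (null_counts >= observed[None, :]).mean(axis=0)
        table["empirical_p"] = exceed
        table.attrs["null_mean"] = null_counts.mean(axis=0).tolist()
    return table.set_index("target")
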