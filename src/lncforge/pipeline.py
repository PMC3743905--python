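"""End-to-end orchestration: simulate -> filter -> classify -> characterize
-> permutation tests -> knockdown screen -> enrichment, with a consolidated
report written to an output directory.

Every threshold appearing in the report is carried in the run config, so a
rerun with the same config (and seed) reproduces the artifacts exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import characterize as chz
from .candidate_filter import FilterConfig, run_filter_cascade
from .enrichment import closest_gene_list, host_gene_list, overlapping_gene_list
from .kd_screen import call_regulation, control_percentile_thresholds, \
    map_probes_to_lncrnas, regulator_summary
from .permutation import (
    IntergenicShuffler,
    imprinted_proximity_test,
    imprinted_loci_involved,
    rank_sum_compare,
    shuffle_intergenic,
    unspliced_est_overlap_test,
)
from .synthetic_data import Fixture, FixtureConfig, generate_fixture

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Declarative pipeline configuration (YAML-serializable)."""

    seed: int = 1
    n_perm: int = 2000
    filter: dict = field(default_factory=dict)
    fixture: dict = field(default_factory=dict)
    requested: tuple = (
        "filter", "characterize", "permtest", "kd_screen", "enrich"
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_all(config: RunConfig | None = None,
            out_dir: str | Path = "lncforge_out",
            fixture: Fixture | None = None) -> dict[str, Any]:
    """Run the full pipeline on a fixture (generated when not supplied).

    Writes stage artifacts under ``out_dir`` and returns the consolidated
    report dict (also written as ``report.json``).
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "n_perm": config.n_perm}

    if fixture is None:
        fx_cfg = FixtureConfig(**config.fixture) if config.fixture else FixtureConfig()
        fixture = generate_fixture(fx_cfg, seed=config.seed)
    fixture.write(out / "fixture")
    report["fixture"] = {
        "n_candidates": len(fixture.candidates),
        "n_genes": len(fixture.genes),
    }

    filter_cfg = FilterConfig(**config.filter) if config.filter else FilterConfig()
    lnc_set, audit = run_filter_cascade(fixture.candidates, fixture.genes, filter_cfg)
    audit.to_frame().to_csv(out / "filter_audit.tsv", sep="\t", index=False)
    report["filter"] = {
        "audit": audit.rows,
        "categories": lnc_set.counts(),
        "thresholds": {
            "min_length": filter_cfg.min_length,
            "expression_threshold": filter_cfg.expression_threshold,
            "cpc_max": filter_cfg.cpc_max,
            "min_coding_distance": filter_cfg.min_coding_distance,
            "keep_class_codes": sorted(filter_cfg.keep_class_codes),
        },
    }

    survivors = lnc_set.all_transcripts()
    if "characterize" in config.requested:
        if "cage" not in fixture.tracks:
            raise KeyError("characterize requested but the 'cage' track is missing")
        table = chz.characterization_report(
            survivors, fixture.tracks, coding_genes=fixture.coding_genes,
            annotation_order=("spliced_est",), peaks_by_mark=fixture.peaks,
        )
        table.to_csv(out / "characterization.tsv", sep="\t")
        finite_cage = table["cage_min_distance"].replace(np.inf, np.nan).dropna()
        report["characterize"] = {
            "spliced_est_rate": float(table["spliced_est_support"].mean()),
            "unspliced_est_rate": float(table["unspliced_est_support"].mean()),
            "repeat_rate": float(table["repeat_flag"].mean()),
            "ribosome_rate": float(table["ribosome_flag"].mean()),
            "median_cage_distance": float(finite_cage.median()),
            "mark_rates": {
                c[len("mark_"):]: float(
                    table.loc[[t.id for t in lnc_set.categories["intergenic"]
                               + lnc_set.categories["intronic"]], c].mean()
                )
                for c in table.columns if c.startswith("mark_")
            },
        }

    if "permtest" in config.requested:
        shuffler = IntergenicShuffler(
            fixture.chrom_sizes, fixture.shuffle_exclusions()
        )
        intergenic = lnc_set.categories["intergenic"]
        imp = imprinted_proximity_test(
            intergenic, fixture.imprinted, shuffler,
            n_perm=config.n_perm, seed=config.seed,
        )
        est = unspliced_est_overlap_test(
            intergenic, fixture.tracks["unspliced_est"], shuffler,
            n_perm=config.n_perm, seed=config.seed + 1,
        )
        cage_obs = chz.cage_min_distances(intergenic, fixture.tracks["cage"])
        permuted_spans = shuffle_intergenic(
            intergenic, fixture.chrom_sizes, fixture.shuffle_exclusions(),
            seed=config.seed + 2,
        )
        cage_perm = chz.cage_min_distances(
            [_interval_as_transcript(iv, i) for i, iv in enumerate(permuted_spans)],
            fixture.tracks["cage"],
        )
        _, cage_p = rank_sum_compare(
            cage_obs[np.isfinite(cage_obs)], cage_perm[np.isfinite(cage_perm)]
        )
        report["permtest"] = {
            "imprinted": {"observed": imp.observed, "p": imp.empirical_p,
                          "p_text": imp.p_text()},
            "imprinted_loci_involved": imprinted_loci_involved(
                intergenic, fixture.imprinted
            ),
            "unspliced_est": {"observed": est.observed, "p": est.empirical_p,
                              "p_text": est.p_text()},
            "cage_rank_sum_p": cage_p,
        }
        pd.DataFrame({"imprinted": imp.permuted, "unspliced_est": est.permuted}) \
            .to_csv(out / "permuted_statistics.tsv", sep="\t", index=False)

    if "kd_screen" in config.requested:
        kd = fixture.kd
        probe_map = map_probes_to_lncrnas(kd.probes, survivors)
        thresholds = control_percentile_thresholds(kd.controls)
        calls = call_regulation(kd.kd, thresholds, probe_map)
        summary = regulator_summary(
            calls, kd.target_type, kd.kd, thresholds,
            n_mapped=len(probe_map), n_perm=min(200, config.n_perm),
            seed=config.seed,
        )
        summary.to_csv(out / "kd_summary.tsv", sep="\t")
        by_type = summary.groupby("type")["affected"].mean()
        top = summary.iloc[0]
        report["kd_screen"] = {
            "n_mapped_probes": len(probe_map),
            "top_regulator": top.name,
            "top_up": int(top["n_up"]),
            "top_down": int(top["n_down"]),
            "protein_mean_affected": float(by_type.get("protein", np.nan)),
            "lncrna_mean_affected": float(by_type.get("lncrna", np.nan)),
        }

    if "enrich" in config.requested:
        closest = closest_gene_list(
            lnc_set.categories["intergenic"], fixture.coding_genes
        )
        hosts = host_gene_list(lnc_set.categories["intronic"], lnc_set)
        partners = overlapping_gene_list(lnc_set.categories["cis_antisense"], lnc_set)
        for name, lst in [("closest_genes", closest), ("host_genes", hosts),
                          ("overlapping_genes", partners)]:
            (out / f"{name}.txt").write_text("\n".join(lst) + "\n")
        report["enrich"] = {
            "n_closest_genes": len(closest),
            "n_host_genes": len(hosts),
            "n_overlapping_genes": len(partners),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _interval_as_transcript(iv, i):
    from .genome_model import TranscriptModel

    return TranscriptModel(f"perm_{i}", iv.chrom, "+",
                           [type(iv)(iv.chrom, iv.start, iv.end, "+")])
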