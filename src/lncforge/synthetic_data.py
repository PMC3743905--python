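"""Synthetic transcriptome fixtures with planted, exactly-known ground truth.

The generator emulates the processed inputs the analysis consumes: a
reference gene annotation, assembled candidate transcripts with class
codes, per-stage expression and coding-potential scores, annotation tracks
(ESTs, repeats, CAGE clusters, ribosome footprints, conservation elements,
imprinted loci, chromatin peaks) and a knockdown microarray experiment.

Every property the analysis measures is *planted by construction*: flags
are realized by placing the corresponding feature (or withholding it), and
transcripts destined to fail a given filter stage violate exactly that
stage's criterion while satisfying all earlier ones. The accompanying
:class:`TruthManifest` is therefore an exact oracle for the cascade,
classifier, characterization rates and knockdown calls.

Geometry is laid out on a deterministic grid: each chromosome is tiled
into 100-kb blocks, each carrying one protein-coding gene; candidate
transcripts occupy fixed, non-overlapping slots relative to their block's
gene, far enough apart that planted TSS-proximal features cannot
contaminate a neighbour's 5-kb window.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    TranscriptModel,
    write_bed,
    write_gtf,
    write_transcript_table,
)
from .kd_screen import KDExperiment, control_percentile_thresholds

__all__ = [
    "FixtureConfig",
    "KDConfig",
    "TruthManifest",
    "Fixture",
    "generate_fixture",
    "generate_kd_experiment",
    "null_calibration_inputs",
    "est_enrichment_fixture",
]

BRAIN_STAGES = ("E14", "E15", "E17")


@dataclass
class KDConfig:
    """Knockdown-screen shape and planted effects.

    The roster mirrors the emulated screen: 40 protein and 226 lncRNA
    knockdown targets, two replicates each, 55 non-experiment control
    profiles, and 187 probes mappable to candidate lncRNAs out of a
    (scaled-down) universe of 2,000 array probes. ``planted_patterns``
    fixes the four headline regulators' up/down counts; remaining targets
    draw Poisson counts around the group means.
    """

    n_protein_targets: int = 40
    n_lncrna_targets: int = 226
    n_controls: int = 55
    n_replicates: int = 2
    n_probes: int = 2000
    n_mapped_probes: int = 187
    probe_len: int = 60
    planted_patterns: tuple = (
        ("Sall4", 81, 2),
        ("Suv39h2", 3, 64),
        ("Iws1", 62, 2),
        ("Ruvbl1", 0, 47),
    )
    protein_lambda_up: float = 11.2
    protein_lambda_down: float = 9.9
    lncrna_lambda: float = 7.8
    lncrna_affected_cap: int = 28
    baseline_log_mean: float = 2.5
    baseline_log_sd: float = 0.4
    control_noise_sd: float = 0.15
    effect_factor: float = 1.3
    replicate_noise_sd: float = 0.0
    percentile_lo: float = 5.0
    percentile_hi: float = 95.0


@dataclass
class FixtureConfig:
    """Study conditions for the default fixture.

    Expression is log-normal with the lncRNA median one tenth of the
    coding-gene median; annotation coverage targets (spliced EST 0.821,
    repeat 0.40, ribosome 0.05, H3K4me3 0.50, ...) are the planted rates
    realized exactly on the survivor set.
    """

    n_chroms: int = 4
    blocks_per_chrom: int = 100
    block_size: int = 100_000
    # gene architecture
    coding_exons: int = 5
    coding_exon_len: int = 300
    coding_intron_len: int = 3000
    # expression model
    stages: tuple = BRAIN_STAGES
    extra_stages: tuple = ("ES",)
    coding_median_rpkm: float = 30.0
    lncrna_median_rpkm: float = 3.0
    log_sigma: float = 0.5
    expression_threshold: float = 0.3
    # survivor composition
    n_intergenic: int = 200
    n_intronic: int = 300
    n_cis_antisense: int = 80
    n_alt_spliced: int = 420
    single_exon_intergenic: int = 30
    # planted per-stage failures
    n_duplicate: int = 100
    n_short: int = 150
    n_single_exon: int = 150
    n_low_expression: int = 150
    n_class_code: int = 150
    n_coding_potential: int = 150
    n_proximity: int = 150
    # annotation coverage targets
    spliced_est_rate: float = 0.821
    unspliced_est_rate_intergenic: float = 0.06
    unspliced_est_rate_other: float = 0.015  # overall survivor rate 2.4%
    repeat_flag_rate: float = 0.40
    ribosome_rate: float = 0.05
    conserved_rate: float = 0.30
    cage_near_rate: float = 0.80
    cage_max_offset: int = 50
    mark_rates: dict = field(
        default_factory=lambda: {
            "H3K4me3": 0.50,
            "CTCF": 0.40,
            "PolII": 0.40,
            "H3K27ac": 0.30,
            "H3K4me1": 0.35,
        }
    )
    # imprinted loci: one gene span per imprinted block
    imprinted_block_period: int = 8
    imprinted_block_offset: int = 4
    n_involved_loci: int = 21
    n_near_imprinted: int = 80
    imprinted_max_dist: int = 100_000
    kd: KDConfig = field(default_factory=KDConfig)
    seed: int = 1

    @property
    def chrom_length(self) -> int:
        return self.blocks_per_chrom * self.block_size

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @property
    def n_survivors(self) -> int:
        return (
            self.n_intergenic + self.n_intronic
            + self.n_cis_antisense + self.n_alt_spliced
        )

    @property
    def n_candidates(self) -> int:
        return self.n_survivors + (
            self.n_duplicate + self.n_short + self.n_single_exon
            + self.n_low_expression + self.n_class_code
            + self.n_coding_potential + self.n_proximity
        )


@dataclass
class TruthManifest:
    """Exact ground truth for a generated fixture."""

    transcripts: dict[str, dict] = field(default_factory=dict)
    expected_audit: list = field(default_factory=list)
    category_ids: dict[str, list[str]] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)
    kd_targets: dict[str, dict] = field(default_factory=dict)
    probe_map: dict[str, str] = field(default_factory=dict)

    def survivors(self) -> list[str]:
        return [tid for tid, rec in self.transcripts.items() if rec["role"] == "survivor"]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


@dataclass
class Fixture:
    """An in-memory fixture bundle (see :func:`generate_fixture`)."""

    config: FixtureConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    candidates: list[TranscriptModel]
    tracks: dict[str, AnnotationSet]
    peaks: dict[str, AnnotationSet]
    imprinted: list[GenomicInterval]
    manifest: TruthManifest
    kd: KDExperiment

    @property
    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "coding"]

    @property
    def noncoding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "noncoding"]

    def shuffle_exclusions(self) -> list[GenomicInterval]:
        """Exclusion set for locus shuffling: repeats plus all gene spans."""
        out = list(self.tracks["repeats"].intervals)
        out.extend(g.span for g in self.genes)
        return out

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(self.candidates, out / "candidates.gtf")
        write_transcript_table(self.candidates, out / "candidates.tsv")
        gene_transcripts = [t for g in self.genes for t in g.transcripts]
        write_gtf(gene_transcripts, out / "genes.gtf")
        pd.DataFrame(
            [(g.id, g.biotype) for g in self.genes], columns=["gene_id", "biotype"]
        ).to_csv(out / "gene_biotypes.tsv", sep="\t", index=False)
        pd.Series(self.chrom_sizes).rename("length").to_csv(
            out / "chrom_sizes.tsv", sep="\t", header=False
        )
        tracks_dir = out / "tracks"
        tracks_dir.mkdir(exist_ok=True)
        for name, track in self.tracks.items():
            write_bed(track, tracks_dir / f"{name}.bed")
        for mark, track in self.peaks.items():
            write_bed(track, tracks_dir / f"peaks_{mark}.bed")
        write_bed(
            AnnotationSet("imprinted", list(self.imprinted)), tracks_dir / "imprinted.bed"
        )
        self.manifest.to_json(out / "manifest.json")
        kd_dir = out / "kd"
        kd_dir.mkdir(exist_ok=True)
        probe_rows = [
            (iv.chrom, iv.start, iv.end, pid, ".", iv.strand)
            for pid, iv in self.kd.probes.items()
        ]
        pd.DataFrame(probe_rows).to_csv(
            kd_dir / "probes.bed", sep="\t", index=False, header=False
        )
        self.kd.controls.to_csv(kd_dir / "controls.tsv", sep="\t")
        kd_wide = pd.concat(self.kd.kd.values(), axis=1)
        kd_wide.to_csv(kd_dir / "kd_profiles.tsv", sep="\t")
        pd.Series(self.kd.target_type).rename("type").to_csv(
            kd_dir / "target_types.tsv", sep="\t", header=False
        )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

class _Layout:
    """Deterministic block grid: per-block gene plus candidate slots."""

    def __init__(self, cfg: FixtureConfig):
        self.cfg = cfg
        self.n_blocks = cfg.n_chroms * cfg.blocks_per_chrom
        period, offset = cfg.imprinted_block_period, cfg.imprinted_block_offset
        self.imprinted_blocks = [
            b for b in range(self.n_blocks)
            if b % cfg.blocks_per_chrom % period == offset
        ]
        imp = set(self.imprinted_blocks)
        buffers = set()
        for b in self.imprinted_blocks:
            for nb in (b - 1, b + 1):
                if 0 <= nb < self.n_blocks and nb not in imp:
                    buffers.add(nb)
        self.buffer_blocks = sorted(buffers)
        self.normal_blocks = [
            b for b in range(self.n_blocks) if b not in imp and b not in buffers
        ]
        self.involved_blocks = self.imprinted_blocks[: cfg.n_involved_loci]

    def chrom_of(self, block: int) -> str:
        return f"chr{block // self.cfg.blocks_per_chrom + 1}"

    def block_start(self, block: int) -> int:
        return (block % self.cfg.blocks_per_chrom) * self.cfg.block_size

    def gene_start(self, block: int) -> int:
        return self.block_start(block) + 30_000

    def gene_strand(self, block: int) -> str:
        return "+" if block % 2 == 0 else "-"

    def gene_exons(self, block: int) -> list[tuple[int, int]]:
        cfg = self.cfg
        gs = self.gene_start(block)
        step = cfg.coding_exon_len + cfg.coding_intron_len
        return [
            (gs + k * step, gs + k * step + cfg.coding_exon_len)
            for k in range(cfg.coding_exons)
        ]

    def gene_end(self, block: int) -> int:
        return self.gene_exons(block)[-1][1]


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size=None):
    return np.exp(np.log(median) + sigma * rng.standard_normal(size))


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def _make_genes(layout: _Layout, rng: np.random.Generator,
                cfg: FixtureConfig) -> list[GeneModel]:
    genes = []
    all_stages = tuple(cfg.stages) + tuple(cfg.extra_stages)
    for b in range(layout.n_blocks):
        chrom = layout.chrom_of(b)
        strand = layout.gene_strand(b)
        exons = [
            GenomicInterval(chrom, s, e, strand) for s, e in layout.gene_exons(b)
        ]
        gid = f"NM_{b:05d}"
        expr = {
            s: float(max(0.3, _lognormal(rng, cfg.coding_median_rpkm, cfg.log_sigma)))
            for s in all_stages
        }
        t = TranscriptModel(
            f"{gid}.1", chrom, strand, exons, class_code="=",
            expression=expr, stage_presence=set(all_stages), gene_id=gid,
        )
        genes.append(GeneModel(gid, "coding", [t]))
        if b % 2 == 1:  # known noncoding gene in the pre-gene desert
            ns = layout.block_start(b) + 10_000
            nstrand = "+" if (b // 2) % 2 == 0 else "-"
            nexons = [
                GenomicInterval(chrom, ns, ns + 400, nstrand),
                GenomicInterval(chrom, ns + 1400, ns + 1800, nstrand),
            ]
            ngid = f"NR_{b:05d}"
            nexpr = {
                s: float(max(0.3, _lognormal(rng, cfg.lncrna_median_rpkm, cfg.log_sigma)))
                for s in all_stages
            }
            nt = TranscriptModel(
                f"{ngid}.1", chrom, nstrand, nexons, class_code="=",
                expression=nexpr, stage_presence=set(all_stages), gene_id=ngid,
            )
            genes.append(GeneModel(ngid, "noncoding", [nt]))
    return genes


def _survivor_expression(rng, cfg, n_stages_min=1):
    stages = list(cfg.stages)
    k = int(rng.integers(n_stages_min, len(stages) + 1))
    order = rng.permutation(len(stages))
    present = {stages[i] for i in order[:k]}
    expr = {
        s: float(max(cfg.expression_threshold,
                     _lognormal(rng, cfg.lncrna_median_rpkm, cfg.log_sigma)))
        if s in present else 0.0
        for s in stages
    }
    return expr, present


def _noncoding_cpc(rng) -> float:
    return float(min(-1.2, -3.0 + rng.standard_normal()))


def _coding_cpc(rng) -> float:
    return float(max(-0.5, 3.0 + rng.standard_normal()))


def generate_fixture(config: FixtureConfig | None = None,
                     seed: int | None = None) -> Fixture:
    """Generate the full fixture bundle deterministically under ``seed``."""
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    layout = _Layout(cfg)
    if cfg.n_involved_loci > len(layout.imprinted_blocks):
        raise ValueError("n_involved_loci exceeds available imprinted blocks")
    if cfg.n_intergenic - cfg.n_near_imprinted > len(layout.normal_blocks):
        raise ValueError("not enough normal blocks for far intergenic survivors")
    if cfg.n_near_imprinted > 4 * max(1, cfg.n_involved_loci):
        raise ValueError(
            "too many near-imprinted survivors for the involved blocks' "
            "four isolated slots each"
        )
    n_slot_failures = (cfg.n_short + cfg.n_single_exon + cfg.n_low_expression
                       + cfg.n_class_code + cfg.n_coding_potential)
    if n_slot_failures > 8 * len(layout.normal_blocks):
        raise ValueError("planted failure counts exceed block slot capacity")

    genes = _make_genes(layout, rng, cfg)
    candidates: list[TranscriptModel] = []
    manifest = TruthManifest()
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"T{counter:05d}"

    def record(t, role, category=None, **flags):
        manifest.transcripts[t.id] = {"role": role, "category": category, **flags}
        candidates.append(t)

    def make_transcript(block, blocks, strand, class_code, expr=None,
                        presence=None, cpc=None, min_stages=1):
        chrom = layout.chrom_of(block)
        if expr is None:
            expr, presence = _survivor_expression(rng, cfg, min_stages)
        exons = [GenomicInterval(chrom, s, e, strand) for s, e in blocks]
        return TranscriptModel(
            new_id(), chrom, strand, exons, class_code=class_code,
            expression=expr, cpc_score=cpc if cpc is not None else _noncoding_cpc(rng),
            stage_presence=presence,
        )

    bs = layout.block_start

    # --- intergenic survivors: near-imprinted first, then one per normal block
    near_slots = [46_000, 57_000, 68_000, 79_000]
    near_assignments = [
        (layout.involved_blocks[i % len(layout.involved_blocks)],
         near_slots[i // len(layout.involved_blocks)])
        for i in range(cfg.n_near_imprinted)
    ]
    far_assignments = [
        (layout.normal_blocks[i], 46_000)
        for i in range(cfg.n_intergenic - cfg.n_near_imprinted)
    ]
    single_exon_left = cfg.single_exon_intergenic
    for idx, (block, slot) in enumerate(near_assignments + far_assignments):
        p = bs(block) + slot
        near = block in layout.involved_blocks
        if not near and single_exon_left > 0:
            single_exon_left -= 1
            blocks = [(p, p + 400)]
            t = make_transcript(block, blocks, "+" if idx % 2 == 0 else "-", "u",
                                min_stages=2)
        else:
            blocks = [(p, p + 300), (p + 700, p + 1000)]
            t = make_transcript(block, blocks, "+" if idx % 2 == 0 else "-", "u")
        record(t, "survivor", "intergenic", near_imprinted=near)

    # --- intronic survivors: inside intron 2 of the block's gene, kept
    # > 1 kb from the cis-antisense slot so planted CAGE clusters cannot
    # shadow a neighbour's TSS
    for i in range(cfg.n_intronic):
        block = i % layout.n_blocks
        exons = layout.gene_exons(block)
        i2 = exons[2][1]  # start of intron between exon 2 and exon 3
        p = i2 + 1_500
        strand = layout.gene_strand(block) if i % 2 == 0 else (
            "-" if layout.gene_strand(block) == "+" else "+"
        )
        t = make_transcript(block, [(p, p + 150), (p + 350, p + 500)], strand, "i")
        record(t, "survivor", "intronic",
               near_imprinted=block in set(layout.imprinted_blocks))

    # --- cis-antisense survivors: exon overlap on the opposite strand
    for i in range(cfg.n_cis_antisense):
        block = i % layout.n_blocks
        exons = layout.gene_exons(block)
        e2s, e2e = exons[2]
        strand = "-" if layout.gene_strand(block) == "+" else "+"
        blocks = [(e2s + 50, e2s + 250), (e2e + 100, e2e + 250)]
        t = make_transcript(block, blocks, strand, "x")
        record(t, "survivor", "cis_antisense", near_imprinted=False)

    # --- alternative-spliced survivors: same-strand exonic overlap
    for i in range(cfg.n_alt_spliced):
        block = i % layout.n_blocks
        exons = layout.gene_exons(block)
        strand = layout.gene_strand(block)
        if i < layout.n_blocks:
            e0s, e0e = exons[0]
            blocks = [(e0s + 100, e0e + 100), (e0e + 300, e0e + 500)]
        else:
            e4s, e4e = exons[-1]
            blocks = [(e4s - 600, e4s - 450), (e4s - 200, e4s + 100)]
        t = make_transcript(block, blocks, strand, "j")
        record(t, "survivor", "alt_spliced", near_imprinted=False)

    survivors = list(candidates)

    # --- planted per-stage failures (each passes all earlier stages) ------
    fail_slot = 0

    def failure_position(span_len):
        nonlocal fail_slot
        block = layout.normal_blocks[fail_slot % len(layout.normal_blocks)]
        slot = 57_000 + 4_000 * (fail_slot // len(layout.normal_blocks))
        fail_slot += 1
        p = bs(block) + slot
        assert slot + span_len < 90_000
        return block, p

    for _ in range(cfg.n_short):  # exonic length 180 <= 200
        block, p = failure_position(400)
        t = make_transcript(block, [(p, p + 90), (p + 200, p + 290)],
                            "+", "u")
        record(t, "fail_min_length")
    for _ in range(cfg.n_single_exon):  # single exon, one stage only
        block, p = failure_position(400)
        expr, _ = _survivor_expression(rng, cfg)
        stage = cfg.stages[int(rng.integers(len(cfg.stages)))]
        expr = {s: (expr[s] if s == stage else 0.0) for s in cfg.stages}
        if expr[stage] == 0.0:
            expr[stage] = cfg.expression_threshold
        t = make_transcript(block, [(p, p + 400)], "+", "u",
                            expr=expr, presence={stage})
        record(t, "fail_single_exon")
    for _ in range(cfg.n_low_expression):  # below threshold in every stage
        block, p = failure_position(700)
        presence = set(cfg.stages[:2])
        expr = {
            s: float(rng.uniform(0.01, cfg.expression_threshold * 0.8))
            if s in presence else 0.0
            for s in cfg.stages
        }
        t = make_transcript(block, [(p, p + 300), (p + 450, p + 700)], "+", "u",
                            expr=expr, presence=presence)
        record(t, "fail_expression")
    for i in range(cfg.n_class_code):  # assembler artifact codes
        block, p = failure_position(700)
        code = ("e", "o", "c")[i % 3]
        t = make_transcript(block, [(p, p + 300), (p + 450, p + 700)], "+", code)
        record(t, "fail_class_code")
    for _ in range(cfg.n_coding_potential):  # coding-like CPC score
        block, p = failure_position(700)
        t = make_transcript(block, [(p, p + 300), (p + 450, p + 700)], "+", "u",
                            cpc=_coding_cpc(rng))
        record(t, "fail_coding_potential")
    for i in range(cfg.n_proximity):  # intergenic but < 1 kb from a coding gene
        block = layout.normal_blocks[i % len(layout.normal_blocks)]
        gap = int(rng.integers(150, 900))
        p = layout.gene_end(block) + gap
        t = make_transcript(block, [(p, p + 250), (p + 400, p + 650)], "+", "u")
        record(t, "fail_coding_proximity")

    # --- duplicates of multi-exon survivors (collapse at the merge stage)
    alt_survivors = [t for t in survivors
                     if manifest.transcripts[t.id]["category"] == "alt_spliced"]
    for i in range(cfg.n_duplicate):
        orig = alt_survivors[i % len(alt_survivors)]
        expr, presence = _survivor_expression(rng, cfg)
        dup = TranscriptModel(
            f"{orig.id}_dup{i:03d}", orig.chrom, orig.strand, list(orig.exons),
            class_code=orig.class_code, expression=expr,
            cpc_score=_noncoding_cpc(rng), stage_presence=presence,
        )
        record(dup, "fail_merge")

    # --- expected audit ---------------------------------------------------
    n0 = len(candidates)
    audit = [("merge", n0, n0 - cfg.n_duplicate)]
    n = n0 - cfg.n_duplicate
    for stage, removed in [
        ("min_length", cfg.n_short),
        ("single_exon", cfg.n_single_exon),
        ("expression", cfg.n_low_expression),
        ("class_code", cfg.n_class_code),
        ("coding_potential", cfg.n_coding_potential),
        ("coding_proximity", cfg.n_proximity),
    ]:
        audit.append((stage, n, n - removed))
        n -= removed
    manifest.expected_audit = audit
    manifest.category_ids = {
        cat: sorted(
            tid for tid, rec in manifest.transcripts.items()
            if rec["role"] == "survivor" and rec["category"] == cat
        )
        for cat in ("intergenic", "intronic", "cis_antisense", "alt_spliced")
    }

    # --- annotation tracks planted on survivor flags ----------------------
    n_surv = len(survivors)
    rng_flags = rng

    def pick(count, pool=None):
        pool = np.arange(n_surv) if pool is None else np.asarray(pool)
        chosen = rng_flags.permutation(pool)[:count]
        mask = np.zeros(n_surv, dtype=bool)
        mask[chosen] = True
        return mask

    intergenic_idx = [
        i for i, t in enumerate(survivors)
        if manifest.transcripts[t.id]["category"] == "intergenic"
    ]
    other_idx = [i for i in range(n_surv) if i not in set(intergenic_idx)]
    tss_group_idx = [
        i for i, t in enumerate(survivors)
        if manifest.transcripts[t.id]["category"] in ("intergenic", "intronic")
    ]

    spliced_mask = pick(round(cfg.spliced_est_rate * n_surv))
    unspliced_mask = pick(
        round(cfg.unspliced_est_rate_intergenic * len(intergenic_idx)), intergenic_idx
    ) | pick(round(cfg.unspliced_est_rate_other * len(other_idx)), other_idx)
    repeat_mask = pick(round(cfg.repeat_flag_rate * n_surv))
    ribosome_mask = pick(round(cfg.ribosome_rate * n_surv))
    conserved_mask = pick(round(cfg.conserved_rate * n_surv))
    cage_mask = pick(round(cfg.cage_near_rate * n_surv))
    mark_masks = {
        mark: pick(round(rate * len(tss_group_idx)), tss_group_idx)
        for mark, rate in cfg.mark_rates.items()
    }

    spliced_est, unspliced_est, repeats, ribosome, cage, conservation = (
        [], [], [], [], [], []
    )
    for b in range(layout.n_blocks):  # background features
        chrom, start = layout.chrom_of(b), bs(b)
        repeats.append(GenomicInterval(chrom, start + 3_000, start + 6_000))
        cage.append(GenomicInterval(chrom, start + 97_000, start + 97_020))
        if b % 2 == 0:
            unspliced_est.append(GenomicInterval(chrom, start + 92_000, start + 93_000))

    peaks: dict[str, list[GenomicInterval]] = {m: [] for m in cfg.mark_rates}
    for i, t in enumerate(survivors):
        rec = manifest.transcripts[t.id]
        e1 = t.exons[0]
        rec["spliced_est"] = bool(spliced_mask[i])
        if spliced_mask[i]:
            spliced_est.append(GenomicInterval(t.chrom, e1.start, e1.end))
        rec["unspliced_est"] = bool(unspliced_mask[i])
        if unspliced_mask[i]:
            sp = t.span
            unspliced_est.append(
                GenomicInterval(t.chrom, sp.start + 100, sp.start + 300)
            )
        rec["repeat"] = bool(repeat_mask[i])
        if repeat_mask[i]:
            rep_len = math.ceil(0.10 * t.exonic_length)
            repeats.append(GenomicInterval(t.chrom, e1.start, e1.start + rep_len))
        rec["ribosome"] = bool(ribosome_mask[i])
        if ribosome_mask[i]:
            ribosome.append(GenomicInterval(t.chrom, e1.start + 50, e1.start + 80))
        rec["conserved"] = bool(conserved_mask[i])
        if conserved_mask[i]:
            score = float(rng_flags.uniform(0.2, 1.0))
            half = e1.start + max(1, e1.length // 2)
            conservation.append(
                GenomicInterval(t.chrom, e1.start, half, score=round(score, 3))
            )
        rec["cage_near"] = bool(cage_mask[i])
        if cage_mask[i]:
            d = int(rng_flags.integers(0, cfg.cage_max_offset + 1))
            tss = t.tss()
            pos = tss + d if t.strand == "+" else tss - d
            if t.strand == "+":
                cage.append(GenomicInterval(t.chrom, pos, pos + 20))
            else:
                cage.append(GenomicInterval(t.chrom, max(0, pos - 19), pos + 1))
            rec["cage_offset"] = d
        rec["marks"] = {}
        for mark, mask in mark_masks.items():
            rec["marks"][mark] = bool(mask[i])
            if mask[i]:
                tss = t.tss()
                peaks[mark].append(
                    GenomicInterval(t.chrom, max(0, tss - 300), tss + 300)
                )

    imprinted = [
        GenomicInterval(
            layout.chrom_of(b), layout.gene_start(b), layout.gene_end(b),
            name=f"imp_{b:05d}",
        )
        for b in layout.imprinted_blocks
    ]

    tracks = {
        "spliced_est": AnnotationSet("spliced_est", spliced_est, priority=4),
        "unspliced_est": AnnotationSet("unspliced_est", unspliced_est),
        "repeats": AnnotationSet("repeats", repeats),
        "ribosome": AnnotationSet("ribosome", ribosome),
        "cage": AnnotationSet("cage", cage),
        "conservation": AnnotationSet("conservation", conservation),
    }
    peak_sets = {m: AnnotationSet(m, ivs) for m, ivs in peaks.items()}

    manifest.rates = {
        "spliced_est": float(spliced_mask.mean()),
        "repeat": float(repeat_mask.mean()),
        "ribosome": float(ribosome_mask.mean()),
        "conserved": float(conserved_mask.mean()),
        "cage_near": float(cage_mask.mean()),
        "unspliced_est_intergenic": float(unspliced_mask[intergenic_idx].mean()),
        "near_imprinted_intergenic": cfg.n_near_imprinted / cfg.n_intergenic,
        "imprinted_loci_involved": cfg.n_involved_loci / len(layout.imprinted_blocks),
        **{f"mark_{m}": float(mask[tss_group_idx].mean())
           for m, mask in mark_masks.items()},
    }

    # --- knockdown experiment ---------------------------------------------
    mapped_pool = [survivors[i] for i in tss_group_idx][: cfg.kd.n_mapped_probes]
    kd, kd_truth = generate_kd_experiment(
        cfg.kd, rng, mapped_pool, layout=layout
    )
    manifest.kd_targets = kd_truth["targets"]
    manifest.probe_map = kd_truth["probe_map"]

    return Fixture(
        config=cfg,
        chrom_sizes=cfg.chrom_sizes,
        genes=genes,
        candidates=candidates,
        tracks=tracks,
        peaks=peak_sets,
        imprinted=imprinted,
        manifest=manifest,
        kd=kd,
    )


def generate_kd_experiment(
    config: KDConfig,
    seed: int | np.random.Generator | None,
    mapped_lncrnas: Sequence[TranscriptModel],
    layout: _Layout | None = None,
) -> tuple[KDExperiment, dict]:
    """Generate a knockdown microarray experiment with planted effects.

    Control profiles draw per-probe log-normal values; KD profiles copy the
    per-probe control median except at planted probes, which are shifted
    beyond the control percentile band by ``effect_factor``. With zero
    replicate noise the planted up/down sets are recovered exactly by the
    calling rules.
    """
    cfg = config
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(mapped_lncrnas) < cfg.n_mapped_probes:
        raise ValueError("not enough lncRNAs to carry the mapped probes")
    mapped = list(mapped_lncrnas)[: cfg.n_mapped_probes]

    probes: dict[str, GenomicInterval] = {}
    probe_map: dict[str, str] = {}
    for i, t in enumerate(mapped):
        pid = f"probe_{i:04d}"
        e1 = t.exons[0]
        probes[pid] = GenomicInterval(t.chrom, e1.start + 20,
                                      e1.start + 20 + cfg.probe_len, t.strand)
        probe_map[pid] = t.id
    n_background = cfg.n_probes - cfg.n_mapped_probes
    if layout is not None:
        for i in range(n_background):
            b = i % layout.n_blocks
            off = 15_000 + 200 * (i // layout.n_blocks)
            start = layout.block_start(b) + off
            probes[f"probe_{cfg.n_mapped_probes + i:04d}"] = GenomicInterval(
                layout.chrom_of(b), start, start + cfg.probe_len
            )
    else:
        for i in range(n_background):
            start = 1_000_000 + 500 * i
            probes[f"probe_{cfg.n_mapped_probes + i:04d}"] = GenomicInterval(
                "chrBG", start, start + cfg.probe_len
            )

    probe_ids = list(probes)
    n_probes = len(probe_ids)
    baseline = cfg.baseline_log_mean + cfg.baseline_log_sd * rng.standard_normal(n_probes)
    controls = 10 ** (
        baseline[:, None]
        + cfg.control_noise_sd * rng.standard_normal((n_probes, cfg.n_controls))
    )
    control_frame = pd.DataFrame(
        controls, index=probe_ids,
        columns=[f"ctrl_{j:02d}" for j in range(cfg.n_controls)],
    )
    thresholds = control_percentile_thresholds(
        control_frame, cfg.percentile_lo, cfg.percentile_hi
    )
    median = np.median(controls, axis=1)
    lnc_probe = {tid: pid for pid, tid in probe_map.items()}
    mapped_ids = [t.id for t in mapped]

    targets: list[tuple[str, str]] = []
    for name, _, _ in cfg.planted_patterns:
        targets.append((name, "protein"))
    for i in range(cfg.n_protein_targets - len(cfg.planted_patterns)):
        targets.append((f"TF{i + len(cfg.planted_patterns) + 1:02d}", "protein"))
    for i in range(cfg.n_lncrna_targets):
        targets.append((f"LKD{i + 1:03d}", "lncrna"))

    planted_counts = {name: (up, down) for name, up, down in cfg.planted_patterns}
    kd_frames: dict[str, pd.DataFrame] = {}
    truth_targets: dict[str, dict] = {}
    for name, ttype in targets:
        if name in planted_counts:
            n_up, n_down = planted_counts[name]
        elif ttype == "protein":
            n_up = int(rng.poisson(cfg.protein_lambda_up))
            n_down = int(rng.poisson(cfg.protein_lambda_down))
        else:
            n_up = int(rng.poisson(cfg.lncrna_lambda))
            n_down = int(rng.poisson(cfg.lncrna_lambda))
            overshoot = n_up + n_down - cfg.lncrna_affected_cap
            if overshoot > 0:
                n_down = max(0, n_down - overshoot)
                overshoot = n_up + n_down - cfg.lncrna_affected_cap
                n_up -= max(0, overshoot)
        chosen = rng.permutation(len(mapped_ids))[: n_up + n_down]
        up_ids = [mapped_ids[i] for i in chosen[:n_up]]
        down_ids = [mapped_ids[i] for i in chosen[n_up:]]
        values = np.tile(median[:, None], (1, cfg.n_replicates))
        for tid in up_ids:
            row = probe_ids.index(lnc_probe[tid])
            values[row, :] = thresholds["hi_value"].iloc[row] * cfg.effect_factor
        for tid in down_ids:
            row = probe_ids.index(lnc_probe[tid])
            values[row, :] = thresholds["lo_value"].iloc[row] / cfg.effect_factor
        if cfg.replicate_noise_sd > 0:
            values = values * 10 ** (
                cfg.replicate_noise_sd
                * rng.standard_normal((n_probes, cfg.n_replicates))
            )
        kd_frames[name] = pd.DataFrame(
            values, index=probe_ids,
            columns=[f"{name}_rep{r + 1}" for r in range(cfg.n_replicates)],
        )
        truth_targets[name] = {"type": ttype, "up": up_ids, "down": down_ids}

    experiment = KDExperiment(
        probes=probes,
        controls=control_frame,
        kd=kd_frames,
        target_type={name: ttype for name, ttype in targets},
    )
    return experiment, {"targets": truth_targets, "probe_map": probe_map}


# ---------------------------------------------------------------------------
# special-purpose fixtures for statistical validation
# ---------------------------------------------------------------------------

def null_calibration_inputs(
    n_lnc: int = 300,
    lnc_length: int = 600,
    n_chroms: int = 2,
    chrom_length: int = 10_000_000,
    locus_period: int = 7,
):
    """Inputs for a no-signal calibration of the imprinted-proximity test.

    Returns ``(chrom_sizes, exclusions, imprinted_loci, lengths)``. The
    observed lncRNA set for each calibration run should itself be drawn
    with the shuffler, so the observed statistic is exchangeable with the
    permutation null by construction.
    """
    block = 100_000
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    exclusions, loci = [], []
    for ci, chrom in enumerate(chrom_sizes):
        for b in range(chrom_length // block):
            start = b * block
            exclusions.append(GenomicInterval(chrom, start + 30_000, start + 43_500))
            exclusions.append(GenomicInterval(chrom, start + 3_000, start + 6_000))
            if b % locus_period == 3:
                loci.append(GenomicInterval(chrom, start + 30_000, start + 43_500))
    lengths = [lnc_length] * n_lnc
    return chrom_sizes, exclusions, loci, lengths


def est_enrichment_fixture(
    n_lnc: int = 150,
    planted_rate: float = 0.30,
    lnc_length: int = 600,
    est_length: int = 1000,
    n_chroms: int = 2,
    chrom_length: int = 10_000_000,
    seed: int = 0,
):
    """A planted unspliced-EST enrichment fixture (~3x over the null).

    Background ESTs cover roughly 10% of the shuffleable space, so a
    random placement overlaps an EST with probability ~0.1; the observed
    lncRNA set is constructed with ``planted_rate`` of its members
    overlapping an EST and the rest placed in EST-free allowed space.

    Returns ``(spans, ests, chrom_sizes, exclusions)``.
    """
    rng = np.random.default_rng(seed)
    block = 100_000
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    exclusions, ests = [], []
    blocks = []
    for chrom in chrom_sizes:
        for b in range(chrom_length // block):
            start = b * block
            exclusions.append(GenomicInterval(chrom, start + 30_000, start + 43_500))
            exclusions.append(GenomicInterval(chrom, start + 3_000, start + 6_000))
            blocks.append((chrom, start))
            for j in range(5):
                es = start + 50_000 + j * 2_000
                ests.append(GenomicInterval(chrom, es, es + est_length))
    n_planted = round(planted_rate * n_lnc)
    spans = []
    order = rng.permutation(len(ests))
    for i in range(n_planted):
        est = ests[int(order[i % len(order)])]
        s = est.start - 100
        spans.append(GenomicInterval(est.chrom, s, s + lnc_length, name=f"L{i:04d}"))
    for i in range(n_lnc - n_planted):
        chrom, start = blocks[i % len(blocks)]
        s = start + 70_000 + 1_000 * (i // len(blocks))
        assert s + lnc_length < start + 90_000
        spans.append(GenomicInterval(chrom, s, s + lnc_length, name=f"L{n_planted + i:04d}"))
    return spans, AnnotationSet("unspliced_est", ests), chrom_sizes, exclusions
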