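# Methods

This note documents the models, conventions and numerical choices behind
`lncforge`, what the synthetic fixtures do and do not emulate, and the
known limitations.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open `[start, end)`; GTF
(1-based inclusive) is converted at the I/O boundary only. Chromosome
names match by exact string equality, and a cross-chromosome distance is
`inf`. Book-ended intervals have distance 0, so "overlap or closer than
X" filters treat adjacency as proximal. Overlap lengths are computed
against the merged union of the query track, so each base counts at most
once. The TSS of an unstranded transcript defaults to its span start
(single-end libraries lack strand information); a warning is logged.

## The filter cascade

Stage order: redundancy merge → minimum length → single-exon rule →
expression → class code → coding potential → classification → coding
proximity. Interpretations where the criteria leave room:

* **Merge.** Only transcripts with *identical* exon chains are collapsed;
  the representative is the lexicographically smallest id (stable across
  runs and input orders), expression is max-merged per stage and stage
  presence is unioned.
* **Length.** Exonic (spliced) length strictly greater than 200 nt.
* **Single-exon rule.** "Support from at least two developmental time
  points" is read as assembled presence (`stage_presence`), not
  expression above threshold, because the rule applies before the
  expression filter in the cascade.
* **Expression.** A transcript is kept if its *maximum* RPKM over stages
  is ≥ the threshold — the least destructive pooling, consistent with
  per-stage assembly support. The threshold is either a fixed RPKM floor
  (default 0.3) or derived from the average read-mapping rate *m* as the
  nearest-rank percentile of the pooled signal at 100·(1 − *m*) (an 84%
  mapping rate ⇒ 16th percentile). Nearest-rank means the value at rank
  ⌈p/100·n⌉; the rank computation carries a 1e-9 tolerance against float
  artifacts in p itself.
* **Coding potential.** CPC score strictly below −1; a missing score
  fails the filter (conservative).
* **Coding proximity.** Applied only to candidates classified intergenic;
  span-to-span distance to the nearest coding gene must be ≥ 1,000 bp.
  Span-to-span (rather than TSS-to-feature) distance is used for all
  gene-proximity measures.

The audit records `(stage, n_in, n_out)` rows that must telescope; every
removed transcript is attributed to exactly one stage (its first failing
one). The cascade is idempotent and order-invariant in the surviving id
set.

## Classification

Precedence intergenic → intronic → cis-antisense → residual
(alternative-spliced) resolves multi-rule hits and makes the categories a
partition. Intergenic means no span overlap with *any* reference gene,
coding or noncoding. Intron containment is tested against introns of the
union-exon gene model of coding genes (either orientation), avoiding
isoform-dependent ambiguity. Cis-antisense requires ≥ 1 bp exon–exon
overlap with a reference exon on the opposite strand; unstranded
candidates can never be cis-antisense. Antisense partner genes and host
introns are recorded for downstream gene-list construction.

## Characterization

* **Annotation stacking.** A candidate takes the label of the
  highest-priority source covering ≥ 10% of its exonic length (fraction
  measured over the lncRNA's exonic length, not the annotation's), else
  "Unannotated".
* **Conservation.** Per-base scores equal the covering element's score
  and 0 where uncovered; the mean is Σ(score·overlap)/exonic_length, and
  the median is the weighted per-base median. Mean is the default
  statistic; the median variant exists because descriptions of this
  score vary between averaging and medians. Elements are assumed
  disjoint, as conservation-element tracks are.
* **Chromatin marks.** Default criterion: any peak intersecting
  [TSS − 5 kb, TSS + 5 kb). An alternative body-coverage criterion (peak
  bases ≥ 50% of exonic length) is available because "TSS-proximal" and
  "≥ 50% of length" formulations both circulate; both can be reported
  side by side.
* **CAGE.** Strand-agnostic by default (single-end data), distance from
  the TSS to the nearest cluster base, 0 inside a cluster.
* **Matched sampling.** Reference log10(RPKM + ε), ε = 10⁻³, is cut into
  10 quantile bins; per-bin sample counts follow the reference masses via
  largest-remainder apportionment (so with pool = reference and
  n = |reference| the bin masses match exactly), and members are drawn
  uniformly with replacement within bins. An empty pool bin falls back to
  the nearest non-empty bin, logged.

## Permutation tests

Whole spans are shuffled (exon structure is not preserved, mirroring
interval-level shufflers). Placement is sampled *exactly* uniformly over
all valid start positions: the exclusion set (repeats + gene spans) is
complemented into gaps, each gap contributes `max(0, gap − L + 1)` valid
starts for span length L, and a start is drawn by inverse CDF over those
counts. This replaces rejection sampling: identical target distribution,
no retry loop, and a clean error (naming the transcript) when no valid
placement exists. The intronic shuffler works the same way over reference
introns, choosing an intron with probability proportional to its
eligible-start count.

"Within 100 kb" proximity is span distance ≤ 100,000 bp, implemented by
expanding target loci by max_dist + 1 and testing half-open overlap
(exactly equivalent, and vectorizable). The unspliced-EST statistic uses
*span* overlap for both the observed and permuted arms, because the
permuted loci have no exon structure to intersect — an exon-level
observed arm against a span-level null would be biased.

Empirical p is the plain exceedance fraction #{permuted ⋄ observed}/n_perm
(⋄ = ≥ for enrichment); the add-one variant is available for conservative
reporting. p = 0 prints as "< 1/n_perm". Under a true null with a
discrete statistic, ties between observed and permuted values make the
plain fraction mildly conservative; the calibration test accounts for
this by checking uniformity with a KS test at α = 0.01 and the type-I
rate against the exact binomial interval.

The Mann–Whitney comparison uses exact enumeration for tie-free samples
with min size ≤ 8 and the tie-corrected normal approximation otherwise.
The CAGE 5′-completeness comparison ranks observed TSS–cluster distances
against the distances of one permuted replicate set.

## Knockdown screen

Probes map to a lncRNA when > 99% of the probe's bases fall in its exons;
multi-mapping probes map to all hits (flagged). Thresholds are *per-probe*
nearest-rank 5th/95th percentiles across control profiles — not one
global pooled percentile — because per-probe dynamic ranges on arrays
differ by orders of magnitude; a probe whose controls are constant is
uncallable and excluded. The default replicate rule ("both") calls a
lncRNA up only if every replicate of a mapped probe exceeds the upper
threshold (symmetrically for down); a replicate-mean rule is available.
Conflicting calls across a lncRNA's probes resolve to no call.

Self-calibration: feeding the 55 controls back as single-replicate
pseudo-knockdowns calls each probe at exactly 4/55 ≈ 7.3% — the two values
strictly above the rank-53 threshold plus the two strictly below rank 3 —
which is what the nearest-rank construction implies (the naive
5% + 5% = 10% expectation ignores that thresholds are order statistics of
the same sample).

The per-regulator null re-draws the mapped-probe subset uniformly from
the whole probe universe each permutation (one shared draw per
permutation across targets) and counts called probes among them; the
observed affected count is compared against this null for an empirical p.

## Enrichment lists

Intergenic candidates contribute their nearest coding gene at distance
strictly < 500 kb; intronic candidates contribute their host gene unless
the containing intron exceeds 100 kb; cis-antisense candidates contribute
their recorded partners. All lists are deduplicated. Term enrichment is
the hypergeometric upper tail P[X ≥ k] with BH adjustment across tested
terms; the background defaults to the supplied coding genes (an external
curated-annotation service would use its own background — a documented
divergence).

## Synthetic fixtures

The default fixture models 4 chromosomes × 10 Mb tiled into 100-kb
blocks, each with one 5-exon protein-coding gene (300-bp exons, 3-kb
introns) and, in alternating blocks, a known noncoding gene; 2,000
candidate transcripts occupy fixed slots relative to their block's gene.
Survivors: 200 intergenic (30 single-exon), 300 intronic, 80
cis-antisense, 420 alternative-spliced. Planted failures: 100 duplicates
plus 150 each violating exactly one of length / single-exon / expression /
class-code / coding-potential / proximity while satisfying all earlier
stages, so the audit is an exact oracle.

Expression is log-normal (σ_ln = 0.5) with coding median 30 RPKM and
lncRNA median 3 RPKM — one tenth, the headline expression contrast this
kind of study reports. CPC scores are Normal(−3, 1) truncated below −1.2
for noncoding-like models and Normal(+3, 1) truncated above −0.5 for
coding-like planted failures. Annotation flags are realized exactly:
spliced-EST support 82.1%, repeat overlap 40%, ribosome association 5%,
CAGE-adjacent TSSs 80% (cluster within 0–50 bp), conservation elements on
30%, chromatin-mark rates H3K4me3 50% / CTCF 40% / PolII 40% / H3K27ac
30% / H3K4me1 35% of intergenic + intronic survivors, unspliced-EST
support 6% of intergenic (2.4% overall). Peak-bearing survivors are kept
≥ 10.5 kb apart so a planted peak can never fall into a neighbour's 5-kb
TSS window, which is what makes the planted rates construction-exact.
48 imprinted loci (gene spans of every 8th block) are planted so that
exactly 40% of intergenic survivors lie within 100 kb of a locus and
exactly 21/48 = 43.75% of loci are involved.

The knockdown fixture has 40 protein + 226 lncRNA targets, 2 replicates
each, 55 controls, and 187 mapped probes in a 2,000-probe universe
(scaled down from a 60,000-probe array). Four regulators carry fixed
planted patterns (81 up/2 down; 3/64; 62/2; 0/47); the remaining protein
targets draw Poisson(11.2)/Poisson(9.9) up/down counts and lncRNA targets
Poisson(7.8)/Poisson(7.8) capped at 28 affected, putting the group means
near 25.5 (13.6 up / 11.9 down) and 15.6 affected lncRNAs. Planted
probes are shifted to 1.3× the upper / 0.77× the lower threshold;
unplanted probes sit at the per-probe control median, so with zero
replicate noise recovery is exact; a replicate-noise knob degrades this
gracefully.

Two auxiliary builders support statistical validation:
`null_calibration_inputs` yields a genome, exclusion set and imprinted
loci with *no* planted signal — calibration runs draw the "observed" loci
with the shuffler itself, making observed and permuted statistics
exchangeable by construction; `est_enrichment_fixture` plants a 30%
observed unspliced-EST overlap over a ~10% background null (≈ 3×
enrichment).

**What the fixtures do not emulate:** read-level noise, assembly
fragmentation and chimerism, isoform complexity (one transcript per
gene), overlapping candidate loci, GC/mappability biases in shuffling
space, array normalization artifacts, and real annotation-track error.
Passing tests therefore demonstrate the correctness and calibration of
the *analysis machinery* under known truth, not the biological accuracy
of any particular dataset's results.

## Problem sizes

Default analyses run at fixture scale: 2,000 candidates, 2,000 permutations
for fixture-level tests, 500 permutations × 200 replicate runs for null
calibration, 1,000 permutations for planted-effect recovery, and 100 seeds
for matched-sampling checks. These sizes give the statistical checks
comfortable power while keeping a full run in minutes on one core.

## Known limitations

* Exon-structure-preserving shuffles are not implemented; nulls are
  whole-span.
* The classifier records one containing intron per intronic candidate
  (the first by coordinate) even when isoforms of several genes could
  host it.
* Probe mapping is coordinate-based; sequence-level cross-hybridization
  is out of scope.
* The enrichment stand-in uses a user-supplied term map and background;
  it does not reproduce any curated annotation database's contents.
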