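"""Exclusion-aware permutation tests.

Shuffles the intergenic candidates' spans across the genome (avoiding
repeats and gene bodies, preserving lengths) to build empirical nulls for
two enrichment statistics: proximity to imprinted loci (within 100 kb) and
overlap with unspliced ESTs.
"""

from lncforge import (
    IntergenicShuffler,
    generate_fixture,
    imprinted_proximity_test,
    run_filter_cascade,
    unspliced_est_overlap_test,
)

fixture = generate_fixture(seed=1)
lnc_set, _ = run_filter_cascade(fixture.candidates, fixture.genes)
intergenic = lnc_set.categories["intergenic"]

shuffler = IntergenicShuffler(fixture.chrom_sizes, fixture.shuffle_exclusions())

imp = imprinted_proximity_test(intergenic, fixture.imprinted, shuffler,
                               n_perm=2000, seed=1)
print(f"imprinted proximity: observed {100 * imp.observed:.1f}% of intergenic "
      f"candidates within 100 kb of an imprinted locus")
print(f"  permutation null mean {100 * imp.permuted.mean():.1f}%, "
      f"empirical p {imp.p_text()}")

est = unspliced_est_overlap_test(intergenic, fixture.tracks["unspliced_est"],
                                 shuffler, n_perm=2000, seed=2)
print(f"unspliced ESTs: observed {100 * est.observed:.1f}% overlap, "
      f"null mean {100 * est.permuted.mean():.1f}%, empirical p {est.p_text()}")
print()
print("A p printed as '< 1/n_perm' means no permuted replicate reached the")
print("observed statistic.")
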