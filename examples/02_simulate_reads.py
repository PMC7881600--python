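"""Simulate the sequencing design: HiFi-like long reads at 50X per allele
(the minor allele at one tenth abundance) and 150 bp paired-end short
reads, then print read-set summary statistics.
"""

import allelescope as a
from allelescope.profiling import readset_stats

lib = a.make_library(seed=1)
blueprints = a.builtin_blueprints(lib)
genotype = a.Genotype()  # alleleA 1.0, alleleB 1.0, alleleC 0.1

long_reads = a.simulate_long(
    lib, genotype, a.LongReadModel(seed=2), coverage_per_allele=50,
    blueprints=blueprints,
)
stats = readset_stats(long_reads.reads)
print(f"long reads: {stats['n_reads']}  total {stats['total_bases']:,} bp  "
      f"mean {stats['mean_len']:.2f} bp  max {stats['max_len']:,} bp")
print("reads per allele:")
print(long_reads.truth.allele.value_counts().to_string())

r1, r2 = a.simulate_short(
    lib, genotype, a.ShortReadModel(seed=3), coverage=100, blueprints=blueprints
)
print(f"\nshort reads: {len(r1)} pairs of 150 bp "
      f"({2 * 150 * len(r1):,} bases, ~100X per major allele)")
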