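"""In-silico PCR genotyping, depth profiling and the off-target scan.

A diagnostic primer pair flanking the cut site produces a wild-type-sized
band shifted by +26 bp on the NHEJ allele and no product on the concatemer
allele (the insertion exceeds any amplifiable length) - the in-silico
version of the genotyping gel.  The off-target scan confirms that no read
carrying donor sequence aligns outside the target locus.
"""

import allelescope as a
from allelescope.profiling import PrimerPair, depth_profile, insilico_pcr, off_target_scan
from allelescope.seq_core import revcomp

lib = a.make_library(seed=1)
blueprints = a.builtin_blueprints(lib)
alleles = {n: a.build_allele(lib, bp) for n, bp in blueprints.items()}

wt = alleles["wildtype"].record
pair = PrimerPair(wt.seq[740:760], revcomp(wt.seq[1240:1260]))
for name in ("wildtype", "alleleA", "alleleB"):
    products = insilico_pcr(alleles[name].record, pair)
    print(f"{name:10s} products: {products or 'none (insert too large)'}")

decoys = a.make_decoy_genome(lib, n_chrom=1, lengths=[20000], seed=9)
panel = {d.id: d.seq for d in decoys}
panel["locus"] = lib["CHR17_L"].seq + lib["CHR17_R"].seq
r1, r2 = a.simulate_short(
    lib, a.Genotype(), a.ShortReadModel(seed=11), coverage=10, blueprints=blueprints
)
flagged = off_target_scan(r1.reads[:2000], panel, lib)
print(f"\noff-target reads carrying donor sequence: {len(flagged)} (expected 0)")

profiles = depth_profile(
    r1.reads[:2000], {"template": lib["TEMPLATE"].seq, "puc": lib["PUC"].seq}
)
for name, prof in sorted(profiles.items()):
    print(f"mean depth over {name}: {prof.mean:.1f}")
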