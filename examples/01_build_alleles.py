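"""Build the synthetic segment library and the three edited-locus alleles.

Prints the length of every allele, its template/backbone copy numbers and
the junction inserts of the two complex alleles.  The numbers mirror the
study genotype: a 26 bp NHEJ insertion, a ~38 kb seven-copy concatemer
with one backbone copy, and an 18 kb three-copy deletion derivative.
"""

import allelescope as a

lib = a.make_library(seed=1)
blueprints = a.builtin_blueprints(lib)

print(f"complete template: {lib.template_len} bp "
      "(gRNA site + LHA + SRY + GFP + RHA + gRNA site)")
for name, bp in blueprints.items():
    truth = a.build_allele(lib, bp)
    copies = sum(1 for b in bp.blocks if b.segment_label == "TEMPLATE")
    backbones = sum(
        1 for b in bp.blocks if b.segment_label == "PUC" and b.trunc is None
    )
    print(
        f"{name:14s} {len(truth.record):6d} bp  insertion "
        f"{truth.insertion_length:6d} bp  templates {copies}  backbone {backbones}"
    )

print("\nalleleB junction inserts (5' -> 3'):")
for j in a.build_allele(lib, blueprints["alleleB"]).junctions:
    print(f"  {j.left[0]}{j.left[1]} | {j.right[0]}{j.right[1]}  "
          f"insert {j.insert_len:3d} bp  {j.annotation}")
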