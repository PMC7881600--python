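"""Discover junction sequences from short reads: the terminal 50 bp of the
template and backbone are decomposed into 25-mers, matching reads are
selected, abundance-trimmed, greedily assembled, and the contigs annotated.

Each printed junction shows the flanking blocks and the insert between
them: 20 bp partial gRNA-site footprints at blunt-ligation joints, 56 bp
and 9 bp backbone fragments at two junctions, and empty inserts at the
homology-repaired outer boundaries.
"""

import allelescope as a
import allelescope.junction_finder as jf
from allelescope.structure_caller import CompositeReference

lib = a.make_library(seed=1)
blueprints = a.builtin_blueprints(lib)
r1, r2 = a.simulate_short(
    lib, a.Genotype(), a.ShortReadModel(sub_rate=0.0, seed=7),
    coverage=100, blueprints=blueprints,
)

index = jf.build_edge_index({"template": lib["TEMPLATE"].seq, "puc": lib["PUC"].seq})
selected, counts = jf.select_reads(r1.reads + r2.reads, index)
print(counts.to_string(index=False))
trimmed = jf.error_trim(selected)
contigs = jf.assemble_greedy(trimmed)
print(f"\n{len(selected)} reads selected -> {len(contigs)} contigs")

ref = CompositeReference.from_library(lib)
calls = jf.annotate_contigs(contigs, ref.refs, lib)
seen = set()
for c in calls:
    if c.signature() in seen:
        continue
    seen.add(c.signature())
    print(f"{c.left[0]}{c.left[1]} | {c.right[0]}{c.right[1]}  "
          f"insert {c.insert_len:3d} bp  {c.annotation}")
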