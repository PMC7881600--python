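# allelescope

Resolving the structure of complex CRISPR knock-in alleles from long- and
short-read sequencing.

## The problem

Knock-in strategies that flank a donor cassette with the gRNA target site
(HMEJ, HITI) can produce anything from the intended single-copy insertion
to large concatemers: multiple cassette copies in mixed orientations,
captured plasmid backbone, partial gRNA-site footprints at blunt-ligation
junctions, and deletion derivatives. Standard variant callers do not
reconstruct such alleles. `allelescope` implements a targeted resolution
pipeline for a single edited locus, modelled on a bovine safe-harbor
(H11, chromosome 17) knock-in of a 5.1 kb *SRY*-GFP cassette whose edited
genome carried three alleles: a 26 bp NHEJ insertion, a ~38 kb allele with
seven cassette copies plus one pUC backbone copy, and an 18 kb derivative
missing an internal inverted repeat of four copies.

It is a library for people building or validating locus-resolution
methods: every stage is importable, seeded, and exercised end-to-end on a
synthetic diploid-plus-derivative genotype, so no external data are
needed.

## Method

1. **Recruitment** — long reads are screened against a four-sequence bait
   set (wild-type locus ±1 kb of the cut, plasmid backbone, complete
   cassette, NHEJ allele) with a seed-chain-extend local aligner
   (match +1, mismatch −1, gap open −2, gap extend −1; edit-distance
   polish via edlib).
2. **Block words** — each candidate read is tiled into 1 kb subreads with
   0.5 kb overlap and mapped to a composite reference holding the locus,
   the backbone and a *single* cassette copy. Collinear subread hits merge
   into blocks, so a read becomes a word like `L T+ P+ T−`; every cassette
   traversal is one symbol, which is what makes copy number countable on
   the collapsed reference.
3. **Clustering and chaining** — reads with identical canonical words form
   clusters; cluster words are chained by suffix/prefix overlap, anchored
   at the genomic flanks. A structure is reported when supported by ≥2
   reads from >1 cluster (or by ≥2 reads that each span the whole
   structure). For cassette-free structures the cut-site indel is measured
   by anchor alignment against the wild-type locus.
4. **Junctions** — the terminal 50 nt of cassette and backbone become 26
   overlapping 25-mers each; short reads containing any of them (or their
   reverse complement) are selected, abundance-trimmed, assembled by
   greedy maximal-overlap extension (SSAKE-style, min overlap 16), and the
   contigs annotated by local alignment: block pair, insert sequence, and
   insert class (HR boundary, partial gRNA footprint, backbone fragment).
5. **Consensus** — reads placed uniquely on a structure are grouped per
   junction, trimmed of excess wild-type flank, aligned with a
   centre-star MSA and collapsed by plurality (>0.5) majority rule.

## Worked example

```
python examples/03_resolve_structures.py
```

prints (seed 1):

```
recruited 203 of 203 long reads; 38 block-word clusters

structure_1: L+ T+ P+ T- T- T+ T+ T+ T- R+
  template copies 7, backbone copies 1, insertion ~38 kb (38708 bp), support 146 reads / 32 clusters
structure_2: L+ T+ P+ T+ T- R+
  template copies 3, backbone copies 1, insertion ~18 kb (18132 bp), support 22 reads / 10 clusters
structure_3: LOCUS+
  template copies 0, backbone copies 0, insertion ~0 kb (0 bp), support 50 reads / 1 clusters
  cut-site indel: +26 bp (ACATACGGTTAGGCAATAATCGACGT)
```

`structure_1` is the major concatemer read off its block word: genomic
left flank, cassette, backbone, an inverted-repeat run of cassette copies,
and the right flank — 7 cassette copies, 1 backbone, insertion flooring
to 38 kb. `structure_2` is the deletion derivative (3 copies, 18 kb), and
`structure_3` is the locus-spanning allele whose cut-site refinement
recovers the 26 bp insertion exactly. No wild-type structure is reported.
The other examples demonstrate allele construction, read simulation,
short-read junction discovery (the 56 bp and 9 bp backbone fragments and
the footprint-free outer boundaries are recovered exactly), and in-silico
PCR genotyping (520 bp wild-type band shifting to 546 bp on the NHEJ
allele).

A thin CLI wraps the same pipeline:
`allelescope resolve --seed 1` or `allelescope all --seed 1 --outdir out/`.

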