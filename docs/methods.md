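# Methods

## The system being modelled

A safe-harbor locus is cut once by Cas9 (19 nt protospacer as published,
`TAGCCATAAGACTACCTAT`, plus an NGG PAM; blunt cut 3 bp 5′ of the PAM) and
repaired in the presence of a circular donor: a 5.1 kb "complete
template" (gRNA site + 1 kb left homology arm + 1.8 kb SRY + 1.3 kb GFP +
1 kb right homology arm + gRNA site) carried in a 2.7 kb pUC backbone.
The edited genotype holds three alleles at the locus:

* **alleleA** — wild type plus a 26 bp NHEJ insertion at the cut.
* **alleleB** — a concatemer, block order
  `CHR17_L · T+ · PUC+ · [T− · T− · T+ · T+] · T+ · T− · CHR17_R`:
  seven template copies and one backbone copy, ~38.8 kb of inserted
  sequence. The outer junctions are homology-repaired (no gRNA-site
  footprint; the outermost copies lack their outward-facing site, so each
  contributes 5122 of 5144 bp). Every internal blunt-ligation junction
  carries a 20 bp partial gRNA site, except two adjacent junctions inside
  the bracketed run, which carry 56 bp and 9 bp backbone fragments (the
  two ends of the linearised backbone).
* **alleleC** — alleleB with the bracketed inverted-repeat run (two
  reverse copies then two forward copies, plus its internal junctions)
  deleted: three copies, one backbone, ~18.1 kb. By construction alleleC
  is an exact contiguous-deletion derivative of alleleB.

All component sequences are seeded random stand-ins, generated so that no
25-mer is shared between different segment labels (and none with the gRNA
site); only the protospacer is a real published sequence. This keeps
block-level read classification unambiguous by design — real homology
arms that duplicate genomic flank sequence would blur the outer block
boundaries (see Limitations).

The published figure leaves the exact copy order of the concatemer open;
the order above was chosen, among the orders satisfying every textual
constraint (7 copies, 1 backbone, a deletable middle run of two reverse
plus two forward copies, identical outer ends in B and C), so that the
deletion derivative creates a locally novel junction (backbone followed
directly by a forward copy never occurs in alleleB). The derivative is
then identifiable from ~3-block read placements (5–8 kb spans) rather
than only from rare >11 kb placements, which matters at its one-tenth
coverage. The order is a constructor argument for anyone wanting a
different architecture.

## Synthetic data generator

`read_sim` emulates the study's sequencing design and nothing more:

* **Long reads**: log-normal lengths (mean 15 000 bp, σ = 0.6, min 500,
  cap 60 000), HiFi-like errors by default (substitution 1%, insertion
  0.5%, deletion 0.5%; a CLR-like preset 5/5/3% is provided), constant
  Q20. Each allele is sampled to `coverage × abundance × length` bases
  (default 50X; abundances 1 : 1 : 0.1), with read length capped at the
  allele length — a 2 kb allele therefore yields ~50 full-length reads,
  mirroring locus-spanning reads cut out of longer genomic molecules.
* **Short reads**: 150 bp FR pairs, insert ~N(350, 50²), substitution
  errors only (default 0.1%, or exact), constant Q30, to a configurable
  depth (default 100X per unit abundance).
* **Decoy chromosomes**: random sequence rejected until it shares no
  25-mer with donor segments, for recruitment specificity and the
  off-target scan.

Every read carries a truth record (allele, coordinates, strand). What the
generator does **not** model: chimeric/adapter artifacts, PCR duplicates,
quality-dependent errors, homopolymer bias, and real genomic repeat
context. Passing tests therefore demonstrate the inference logic under
the stated error model, not performance on arbitrary real data.

## Inference chain

**Recruitment.** Local alignment is seed (15-mer) → diagonal chain →
edlib polish of the chained window, trimmed to the best-scoring run
(Kadane over cigar runs) so windows with unaligned overhangs become
proper local hits. Scores use match +1 / mismatch −1 / gap open −2 / gap
extend −1; N matches nothing. A read is recruited with a hit of ≥500 bp
and ≥0.8 identity to any of the four baits (defaults chosen so 1%-error
15 kb reads recruit reliably and decoy reads never do).

**Block words.** Reads are tiled into 1 kb subreads stepping 500 bp (the
trailing fragment merges into the last window, so every subread is ≥500
bp). Each subread takes its best composite-reference hit (≥300 aligned
bp, ≥0.7 identity; ties: score, then lexicographic label, then leftmost).
Consecutive hits with the same label and orientation merge when reference
coordinates advance with the read (tolerance 200 bp + 2% drift; small
negative jitter from subread overlap is tolerated; unmapped subreads do
not break a block). A tandem-copy boundary appears as a coordinate reset
and is never merged, so each traversal of the collapsed template is one
block. Blocks under 300 bp of read span are dropped as tiling noise.
Locus blocks are symbolised by position relative to the cut (left flank,
right flank, or cut-spanning).

**Clustering.** Words are canonicalised against their reverse complement
(reversed order, flipped orientations); identical canonical words form a
cluster.

**Structure assembly.** Cluster words (both orientations) seed chains at
the left-flank anchor and extend by suffix/prefix overlap: all extensions
overlapping by ≥3 symbols branch; 2-symbol overlaps are used only when no
longer overlap exists (this resolves same-orientation repeat runs, whose
words are locally ambiguous at 2-gram level, while still allowing the
low-coverage derivative to complete from 3-gram evidence). Chains
complete at the right-flank anchor; completed words embedding another
completed word are dropped as chimeras. Support counts reads whose word
is a contiguous subword; a structure is reported with ≥2 supporting reads
from ≥2 clusters, or with ≥2 reads each spanning the entire structure
(the single-block NHEJ allele collapses into one canonical cluster, which
the multi-cluster rule alone could never accept; a full-span read
corroborates the whole structure by itself). A structure with no uniquely
supporting read is flagged ambiguous. Insertion length is the sum of
full reference lengths over insert symbols — junction microinserts
(9–56 bp) are below block resolution, so the value is exact to well
under 1 kb and is also reported floored to kb.

**Cut-site indel.** For template-free structures, two 200 bp wild-type
anchors offset 30 bp from the cut are located in each supporting read
(edlib infix mode, both orientations); the anchor gap minus the wild-type
gap is the per-read indel, the call is the median, and the inserted
sequence is the modal read subsequence between the anchors. The offset
keeps the anchors intact for deletions up to ~30 bp on either side.

**Junction discovery.** Both 50 bp edges of template and backbone give 26
overlapping 25-mers each; selection is exact containment of any k-mer or
its reverse complement. Trimming counts strand-canonical 25-mers within
the selected set and truncates each read at the first base covered only
by k-mers below abundance 3 (cutoff 1 is the identity). Greedy assembly
follows the classic SSAKE scheme: seed = unused read of highest summed
k-mer abundance (ties: longest, then lexicographic); extend 3′ then 5′ by
the unused read with the longest exact overlap ≥16 (ties: abundance, then
lexicographic); reads are used once; output is invariant to input order.
Contig annotation aligns contigs to the panel; flanking hits ≥60 bp
delimit a junction and the gap is classified against the gRNA site and
the backbone. Because the gRNA site both terminates every template copy
and prefixes every footprint insert, raw alignment boundaries at
same-orientation junctions are ambiguous; boundaries are therefore
re-derived by exact-match walks anchored at the unique far end of each
hit, which yields exact insert lengths (0/9/20/56) on error-free data.
With sequencing errors the walks stop early and insert lengths degrade
gracefully; the discovery stage is intended to run on high-depth,
effectively error-free (trimmed) short reads, as in the study.

**Consensus.** Reads with exactly one placement of their word on a
structure are grouped per junction; genomic flank blocks are clipped to
200 bp beyond the junction (enough anchor to align, little enough to keep
the alignment informative). Centre-star MSA: the centre maximises summed
pairwise identity (groups subsampled to the longest 12–30 reads for
tractability), pairwise edlib alignments are merged column-wise under
"once a gap, always a gap". Consensus emits, per column with a non-gap
majority, the most frequent residue when its frequency among non-gap
entries exceeds the plurality (0.5), ties broken A<C<G<T.

## Numerical and degenerate-input choices

0-based half-open coordinates throughout; minus-strand hits report
forward-strand target spans. Empty read sets are empty results, not
errors; malformed FASTQ raises a parse error naming the line. All
randomness flows from `numpy.random.default_rng(seed)`; identical config
and seed reproduce byte-identical outputs, which the tests assert.

Problem sizes used by the test-suite and the acceptance script: the
default genotype at 50X long-read coverage (~200 reads, ~2.2 Mb) and 100X
error-free short reads (~15 000 pairs) — the same design the study
describes, scaled to its single locus.

## Limitations

* Segments are mutually 25-mer-disjoint random sequences; real homology
  arms duplicate genomic flank sequence, which would make the outer block
  boundaries (and the "no footprint" call there) harder than modelled.
* Copy number is counted from block words, so two architectures sharing
  every ≤k-block subword (k the longest read span in blocks) cannot be
  distinguished; at 15 kb reads this resolves the published 7/3-copy pair
  but would not resolve, e.g., very long uniform tandem arrays.
* The greedy assembler can in principle chimerise reads from junctions
  sharing >16 bp of context; with 150 bp reads and ~125 bp shared edge
  context this was not observed at tested depths, and junction
  deduplication is signature-based.
* The depth profiler assigns each read wholly to its best reference
  (no multi-mapping split), so depth ratios between references sharing
  sequence are directional, not calibrated.
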