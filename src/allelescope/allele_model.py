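"""Synthetic segment library and ground-truth allele construction.

The study system is a safe-harbor locus on bovine chromosome 17 edited with
a donor plasmid that carries a 5.1 kb cassette ("complete template"):
gRNA target site + 1 kb left homology arm + 1.8 kb SRY + 1.3 kb GFP +
1 kb right homology arm + gRNA target site, all inside a 2.7 kb pUC
backbone.  Repair produced three alleles at the locus:

* ``alleleA`` - the wild-type locus with a 26 bp NHEJ insertion at the cut,
* ``alleleB`` - a ~38 kb concatemer: seven copies of the complete template
  in mixed orientations plus one copy of the plasmid backbone,
* ``alleleC`` - an 18 kb derivative of B missing a middle inverted-repeat
  run of four template copies (two reverse, then two forward).

All component sequences here are random stand-ins generated from a seed;
only the printed gRNA protospacer is used verbatim.  Segments are built so
that no 25-mer is shared between different labels, which makes block-level
read classification well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seq_core import InputError, SeqRecord, kmers, revcomp, write_bed

# printed protospacer (19 nt) + NGG PAM; blunt cut 3 bp 5' of the PAM
GRNA_PROTOSPACER = "TAGCCATAAGACTACCTAT"
GRNA_PAM = "TGG"
GRNA_SITE_SEQ = GRNA_PROTOSPACER + GRNA_PAM

DEFAULT_LENGTHS = {
    "CHR17_L": 1000,
    "CHR17_R": 1000,
    "LHA": 1000,
    "SRY": 1800,
    "GFP": 1300,
    "RHA": 1000,
    "PUC": 2700,
    "NHEJ_INSERT": 26,
    "DECOY": 1000,
}

#: length of the partial gRNA-site remnant left at blunt-ligation junctions
FOOTPRINT_LEN = 20
#: lengths of the two plasmid-backbone fragments captured at junctions 5/6
PUC_FRAGMENTS = (56, 9)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(KeyError):
    """A required segment or blueprint is missing."""


@dataclass
class Segment:
    label: str
    seq: str
    role: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Block:
    """One oriented, optionally truncated segment inside an allele.

    ``trunc`` is a 0-based half-open sub-interval of the segment; orientation
    '-' emits the reverse complement of the (truncated) segment.
    """

    segment_label: str
    orientation: str = "+"
    trunc: Optional[tuple[int, int]] = None

    def emit(self, lib: "SegmentLibrary") -> str:
        seg = lib[self.segment_label]
        lo, hi = self.trunc if self.trunc is not None else (0, len(seg))
        if not (0 <= lo <= hi <= len(seg)):
            raise InputError(
                f"trunc {self.trunc} outside segment {self.segment_label} "
                f"of length {len(seg)}"
            )
        sub = seg.seq[lo:hi]
        return revcomp(sub) if self.orientation == "-" else sub


@dataclass
class AlleleBlueprint:
    """Ordered oriented blocks defining one allele of the edited locus."""

    name: str
    blocks: list[Block]
    cut_site: int = 1000
    circular: bool = False


@dataclass
class SegmentLibrary:
    """Seeded map of segment label -> random synthetic sequence.

    The complete template is registered as the derived entry ``TEMPLATE``
    so blueprints can reference whole cassette copies as single blocks.
    """

    segments: dict[str, Segment]
    seed: int

    def __getitem__(self, label: str) -> Segment:
        try:
            return self.segments[label]
        except KeyError:
            raise ConfigurationError(f"segment {label!r} missing from library")

    def __contains__(self, label: str) -> bool:
        return label in self.segments

    @property
    def template_len(self) -> int:
        return len(self["TEMPLATE"])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _kmer_set(seq: str, k: int = 25) -> set[str]:
    return set(kmers(seq, k)) | set(kmers(revcomp(seq), k))


def make_library(
    seed: int, length_overrides: Optional[dict[str, int]] = None
) -> SegmentLibrary:
    """Deterministic random segment library.

    Segments are redrawn until no 25-mer (either strand) is shared between
    different labels, so every block of an allele has an unambiguous origin.
    """
    lengths = dict(DEFAULT_LENGTHS)
    if length_overrides:
        for label, n in length_overrides.items():
            if n <= 0:
                raise InputError(f"length override for {label} must be positive")
            lengths[label] = n
    rng = np.random.default_rng(seed)
    roles = {
        "CHR17_L": "genomic flank 5' of the cut site",
        "CHR17_R": "genomic flank 3' of the cut site",
        "LHA": "left homology arm",
        "SRY": "sex-determining region Y cassette",
        "GFP": "GFP reporter cassette",
        "RHA": "right homology arm",
        "PUC": "plasmid backbone",
        "NHEJ_INSERT": "small insertion at the cut site",
        "DECOY": "unrelated genomic decoy",
    }
    segments: dict[str, Segment] = {}
    used: set[str] = _kmer_set(GRNA_SITE_SEQ, 15)  # keep the site unique too
    for label in DEFAULT_LENGTHS:
        n = lengths[label]
        while True:
            seq = _random_seq(rng, n)
            ks = _kmer_set(seq, 25) if n >= 25 else _kmer_set(seq, min(n, 15))
            if (ks & used) or (_kmer_set(seq, 15) & _kmer_set(GRNA_SITE_SEQ, 15)):
                continue
            break
        used |= ks
        segments[label] = Segment(label, seq, roles.get(label, ""))
    segments["GRNA_SITE"] = Segment(
        "GRNA_SITE", GRNA_SITE_SEQ, "protospacer + PAM at the H11 cut site"
    )
    lib = SegmentLibrary(segments, seed)
    template = build_complete_template(lib)
    segments["TEMPLATE"] = Segment("TEMPLATE", template.seq, "complete donor cassette")
    return lib


def build_complete_template(lib: SegmentLibrary) -> SeqRecord:
    """gRNA site + LHA + SRY + GFP + RHA + gRNA site (~5.1 kb by default)."""
    parts = ["GRNA_SITE", "LHA", "SRY", "GFP", "RHA", "GRNA_SITE"]
    seq = "".join(lib[p].seq for p in parts)
    return SeqRecord("complete_template", seq)


# ---------------------------------------------------------------------------
# truth emission
# ---------------------------------------------------------------------------


@dataclass
class TruthBlock:
    label: str
    orientation: str
    start: int  # allele coordinates, 0-based half-open
    end: int
    is_insert: bool  # True for short junction inserts (<100 bp)


@dataclass
class TruthJunction:
    left: tuple[str, str]  # (label, orientation) of the block 5' of the joint
    right: tuple[str, str]
    pos: int  # allele coordinate where the left block ends
    insert_len: int
    insert_seq: str
    annotation: str  # HR_boundary / partial_gRNA_footprint / backbone_fragment / cutsite_insert / unknown


@dataclass
class AlleleTruth:
    record: SeqRecord
    blocks: list[TruthBlock]
    junctions: list[TruthJunction]

    @property
    def insertion_span(self) -> tuple[int, int]:
        """Span between the outer genomic flank boundaries."""
        ins = [b for b in self.blocks if not b.label.startswith("CHR17")]
        if not ins:
            mid = next(b.end for b in self.blocks if b.label == "CHR17_L")
            return (mid, mid)
        return (min(b.start for b in ins), max(b.end for b in ins))

    @property
    def insertion_length(self) -> int:
        lo, hi = self.insertion_span
        return hi - lo

    def to_bed(self, path) -> None:
        rows = [
            (self.record.id, b.start, b.end, b.label, 0, b.orientation)
            for b in self.blocks
        ]
        write_bed(rows, path)


def _annotate_insert(seq: str, lib: SegmentLibrary) -> str:
    if not seq:
        return "HR_boundary"
    site = GRNA_SITE_SEQ
    if seq in site or revcomp(seq) in site:
        return f"partial_gRNA_footprint({len(seq)})"
    puc = lib["PUC"].seq
    if seq in puc or revcomp(seq) in puc:
        return f"backbone_fragment({len(seq)})"
    return "unknown"


def build_allele(lib: SegmentLibrary, bp: AlleleBlueprint) -> AlleleTruth:
    """Emit the allele sequence plus per-block and per-junction truth."""
    pieces: list[str] = []
    blocks: list[TruthBlock] = []
    pos = 0
    for blk in bp.blocks:
        seq = blk.emit(lib)
        is_insert = len(seq) < 100 and not blk.segment_label.startswith("CHR17")
        blocks.append(
            TruthBlock(blk.segment_label, blk.orientation, pos, pos + len(seq), is_insert)
        )
        pieces.append(seq)
        pos += len(seq)
    record = SeqRecord(bp.name, "".join(pieces))
    junctions: list[TruthJunction] = []
    major = [b for b in blocks if not b.is_insert]
    for left, right in zip(major, major[1:]):
        between = [b for b in blocks if left.end <= b.start and b.end <= right.start]
        ins_seq = record.seq[left.end : right.start]
        if left.label.startswith("CHR17") and right.label.startswith("CHR17"):
            ann = "cutsite_insert" if ins_seq else "wildtype_joint"
        elif between and between[0].label == "NHEJ_INSERT":
            ann = "cutsite_insert"
        else:
            ann = _annotate_insert(ins_seq, lib)
        junctions.append(
            TruthJunction(
                (left.label, left.orientation),
                (right.label, right.orientation),
                left.end,
                len(ins_seq),
                ins_seq,
                ann,
            )
        )
    return AlleleTruth(record, blocks, junctions)


# ---------------------------------------------------------------------------
# the built-in allele designs
# ---------------------------------------------------------------------------


def _g_footprint() -> Block:
    return Block("GRNA_SITE", "+", (0, FOOTPRINT_LEN))


def builtin_blueprints(lib: SegmentLibrary) -> dict[str, AlleleBlueprint]:
    """Blueprints for the wild type, the three observed alleles and the donor.

    The concatemer order of ``alleleB`` is
    ``CHR17_L . T+ . PUC+ . [T- . T- . T+ . T+] . T+ . T- . CHR17_R``
    with the bracketed inverted-repeat run being the unit whose deletion
    yields ``alleleC``.  The outermost template copies lack their
    outward-facing gRNA site (homology-directed repair leaves no footprint
    at the genomic boundaries); every internal blunt-ligation junction keeps
    a 20 bp partial gRNA site except two adjacent junctions inside the
    deletion unit, which carry 56 bp and 9 bp backbone fragments instead.
    """
    tlen = lib.template_len
    g = len(GRNA_SITE_SEQ)
    outer_plus = Block("TEMPLATE", "+", (g, tlen))  # leading gRNA site absent
    outer_minus = Block("TEMPLATE", "-", (g, tlen))  # emitted rc; genomic side clean
    puc_len = len(lib["PUC"])
    frag56 = Block("PUC", "+", (0, PUC_FRAGMENTS[0]))
    frag9 = Block("PUC", "+", (puc_len - PUC_FRAGMENTS[1], puc_len))

    b_blocks = [
        Block("CHR17_L"),
        outer_plus,
        _g_footprint(),
        Block("PUC"),
        _g_footprint(),
        Block("TEMPLATE", "-"),
        _g_footprint(),
        Block("TEMPLATE", "-"),
        frag56,
        Block("TEMPLATE", "+"),
        frag9,
        Block("TEMPLATE", "+"),
        _g_footprint(),
        Block("TEMPLATE", "+"),
        _g_footprint(),
        outer_minus,
        Block("CHR17_R"),
    ]
    # alleleC = alleleB with the contiguous run T-,T-,T+,T+ (and its internal
    # junction inserts) removed: indices 5..12 of b_blocks.
    c_blocks = b_blocks[:5] + b_blocks[13:]

    blueprints = {
        "wildtype": AlleleBlueprint("wildtype", [Block("CHR17_L"), Block("CHR17_R")]),
        "alleleA": AlleleBlueprint(
            "alleleA", [Block("CHR17_L"), Block("NHEJ_INSERT"), Block("CHR17_R")]
        ),
        "alleleB": AlleleBlueprint("alleleB", b_blocks),
        "alleleC": AlleleBlueprint("alleleC", c_blocks),
        "donor_plasmid": AlleleBlueprint(
            "donor_plasmid", [Block("TEMPLATE"), Block("PUC")], circular=True
        ),
    }
    return blueprints


def template_copy_count(bp: AlleleBlueprint) -> int:
    """Number of (near-)complete template copies in a blueprint."""
    return sum(1 for blk in bp.blocks if blk.segment_label == "TEMPLATE")
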