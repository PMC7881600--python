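"""Junction discovery from short reads by edge k-mer baiting.

The terminal 50 nt of each end ("edge") of the plasmid backbone and of the
complete donor template are decomposed into overlapping 25-mers; any short
read containing one of these k-mers, or its reverse complement, must sit
near a block boundary of an edited allele.  The selected reads are
abundance-trimmed (a light reimplementation of k-mer spectral error
trimming), assembled into contigs by greedy maximal-overlap extension in
the SSAKE style, and the contigs are annotated by local alignment against
the reference panel: two flanking hits with an unaligned gap between them
define a junction, and the gap sequence is classified as a partial gRNA
target-site footprint, a plasmid backbone fragment, an empty
homology-repair boundary, or unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .allele_model import GRNA_SITE_SEQ, SegmentLibrary
from .seq_core import InputError, SeedIndex, SeqRecord, align_local, kmers, revcomp

DEFAULT_EDGE_LEN = 50
DEFAULT_K = 25
DEFAULT_ABUNDANCE_CUTOFF = 3
DEFAULT_MIN_OVERLAP = 16
#: a contig alignment shorter than this is treated as junction insert, not a block
MIN_BLOCK_SIDE = 60


@dataclass
class EdgeKmerIndex:
    """25-mers of every 50 bp reference edge, plus reverse complements."""

    k: int
    edge_len: int
    edges: dict[str, list[str]]  # edge id -> forward k-mers
    lookup: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lookup = {}
        for edge_id, kms in self.edges.items():
            for km in kms:
                self.lookup.setdefault(km, set()).add(edge_id)
                self.lookup.setdefault(revcomp(km), set()).add(edge_id)


def build_edge_index(
    refs: dict[str, str],
    edge_len: int = DEFAULT_EDGE_LEN,
    k: int = DEFAULT_K,
) -> EdgeKmerIndex:
    """Index the two edges of every (linear) reference sequence."""
    if edge_len < k:
        raise InputError("edge_len must be >= k")
    edges = {}
    for name, seq in refs.items():
        if len(seq) < edge_len:
            raise InputError(f"reference {name!r} shorter than edge_len")
        edges[f"{name}:start"] = kmers(seq[:edge_len], k)
        edges[f"{name}:end"] = kmers(seq[-edge_len:], k)
    return EdgeKmerIndex(k=k, edge_len=edge_len, edges=edges)


def select_reads(
    reads: Sequence[SeqRecord], index: EdgeKmerIndex
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Reads containing at least one edge k-mer (either strand).

    Returns the selected reads and a per-edge selected-read count table.
    """
    k = index.k
    lookup = index.lookup
    selected = []
    counts: dict[str, int] = {e: 0 for e in index.edges}
    for read in reads:
        seq = read.seq
        hit_edges: set[str] = set()
        for i in range(len(seq) - k + 1):
            edges = lookup.get(seq[i : i + k])
            if edges:
                hit_edges |= edges
        if hit_edges:
            selected.append(read)
            for e in hit_edges:
                counts[e] += 1
    table = pd.DataFrame(
        sorted(counts.items()), columns=["edge", "n_selected_reads"]
    )
    return selected, table


def _canon(km: str) -> str:
    rc = revcomp(km)
    return km if km <= rc else rc


def error_trim(
    reads: Sequence[SeqRecord],
    abundance_cutoff: int = DEFAULT_ABUNDANCE_CUTOFF,
    k: int = DEFAULT_K,
) -> list[SeqRecord]:
    """Truncate reads at the first base covered only by rare k-mers.

    K-mer abundances are counted within the selected read set itself
    (strand-canonical).  A base is solid while at least one k-mer covering
    it reaches the cutoff; the read is cut at the first non-solid base and
    dropped entirely if fewer than k bases remain.
    """
    if abundance_cutoff < 1:
        raise InputError("abundance cutoff must be >= 1")
    counts: dict[str, int] = {}
    per_read: list[list[str]] = []
    for read in reads:
        kms = kmers(read.seq, k)
        per_read.append(kms)
        for km in kms:
            c = _canon(km)
            counts[c] = counts.get(c, 0) + 1
    out = []
    for read, kms in zip(reads, per_read):
        if not kms:
            continue
        solid = [counts[_canon(km)] >= abundance_cutoff for km in kms]
        n = len(read.seq)
        cut = n
        for pos in range(n):
            lo = max(0, pos - k + 1)
            hi = min(pos, n - k)
            if not any(solid[lo : hi + 1]):
                cut = pos
                break
        if cut >= k:
            qual = read.qual[:cut] if read.qual is not None else None
            out.append(SeqRecord(read.id, read.seq[:cut], qual))
    return out


# ---------------------------------------------------------------------------
# greedy assembly (SSAKE style)
# ---------------------------------------------------------------------------


def _read_weight(seq: str, counts: dict[str, int], k: int) -> int:
    return sum(counts.get(_canon(km), 0) for km in kmers(seq, k))


def assemble_greedy(
    reads: Sequence[SeqRecord],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    k: int = DEFAULT_K,
) -> list[SeqRecord]:
    """Greedy maximal-overlap contig assembly with deterministic tie-breaks.

    The seed is the unused read with the highest summed k-mer abundance
    (ties: longest, then lexicographically smallest sequence).  The contig
    is extended 3' and then 5' by the unused read (either orientation) with
    the longest exact suffix/prefix overlap >= ``min_overlap``; overlap ties
    go to the higher-abundance read, then the lexicographically smaller
    sequence.  Each read is used at most once.
    """
    if min_overlap < 11:
        raise InputError("min_overlap must be >= 11")
    counts: dict[str, int] = {}
    for read in reads:
        for km in kmers(read.seq, k):
            c = _canon(km)
            counts[c] = counts.get(c, 0) + 1
    entries = []  # (idx, seq, rc_seq, weight)
    for i, read in enumerate(reads):
        w = _read_weight(read.seq, counts, k)
        entries.append((i, read.seq, revcomp(read.seq), w))
    # prefix index: first min_overlap bases of each orientation -> entry ids
    pref: dict[str, list[tuple[int, int]]] = {}  # key -> [(idx, orient)]
    for i, seq, rc, _ in entries:
        if len(seq) >= min_overlap:
            pref.setdefault(seq[:min_overlap], []).append((i, 0))
            pref.setdefault(rc[:min_overlap], []).append((i, 1))
    used = [False] * len(entries)
    weights = {i: w for i, _, _, w in entries}
    seqs = {(i, 0): s for i, s, _, _ in entries}
    seqs.update({(i, 1): r for i, _, r, _ in entries})

    def best_extension(contig: str) -> Optional[tuple[int, int, int]]:
        """(overlap, idx, orient) of the best 3' extension of ``contig``."""
        max_o = min(len(contig), max((len(s) for _, s, _, _ in entries), default=0))
        for o in range(max_o, min_overlap - 1, -1):
            key = contig[-o:][:min_overlap]
            cands = []
            for idx, orient in pref.get(key, []):
                if used[idx]:
                    continue
                s = seqs[(idx, orient)]
                if len(s) > o and s[:o] == contig[-o:]:
                    cands.append((-weights[idx], s, idx, orient))
            if cands:
                cands.sort()
                _, s, idx, orient = cands[0]
                return o, idx, orient
        return None

    order = sorted(
        entries, key=lambda e: (-e[3], -len(e[1]), e[1])
    )  # seeding priority
    contigs = []
    n_contig = 0
    for i, seed_seq, _, _ in order:
        if used[i]:
            continue
        used[i] = True
        contig = seed_seq
        for _direction in (3, 5):
            while True:
                ext = best_extension(contig)
                if ext is None:
                    break
                o, idx, orient = ext
                used[idx] = True
                contig += seqs[(idx, orient)][o:]
            contig = revcomp(contig)  # now extend the other end
        # the two reversals cancel: contig is back in seed orientation
        n_contig += 1
        contigs.append(SeqRecord(f"contig_{n_contig}", contig))
    return contigs


# ---------------------------------------------------------------------------
# contig annotation
# ---------------------------------------------------------------------------


@dataclass
class JunctionCall:
    contig_id: str
    left: tuple[str, str, int]  # (block label, orientation, ref end coord)
    right: tuple[str, str, int]  # (block label, orientation, ref start coord)
    insert_seq: str
    annotation: str

    @property
    def insert_len(self) -> int:
        return len(self.insert_seq)

    def signature(self) -> tuple:
        """Orientation-free identity of the junction for deduplication."""
        fwd = (self.left[:2], self.right[:2], self.insert_seq)
        flip = {"+": "-", "-": "+"}
        rc = (
            (self.right[0], flip[self.right[1]]),
            (self.left[0], flip[self.left[1]]),
            revcomp(self.insert_seq),
        )
        return min(fwd, rc)


def _block_label(target_id: str, strand: str, t_span: tuple[int, int], cut: int):
    if target_id == "chr17":
        name = "CHR17_L" if t_span[1] <= cut + 50 else "CHR17_R"
        if t_span[0] <= cut - 50 and t_span[1] >= cut + 50:
            name = "CHR17"
        return name, strand
    if target_id == "template":
        return "TEMPLATE", strand
    if target_id == "puc":
        return "PUC", strand
    return target_id, strand


def annotate_insert(seq: str, lib: SegmentLibrary) -> str:
    if not seq:
        return "HR_boundary"
    if seq in GRNA_SITE_SEQ or revcomp(seq) in GRNA_SITE_SEQ:
        return f"partial_gRNA_footprint({len(seq)})"
    puc = lib["PUC"].seq
    if seq in puc or revcomp(seq) in puc:
        return f"backbone_fragment({len(seq)})"
    return "unknown"


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _walk_block_end(contig: str, target: str, hit) -> tuple[int, int]:
    """Exact-extend a left-flanking hit 3' from its (unique) start anchor.

    Returns (contig position where the block ends, target end coordinate).
    """
    q = hit.query_span[0]
    if hit.strand == "+":
        t = hit.target_span[0]
        while q < len(contig) and t < len(target) and contig[q] == target[t]:
            q += 1
            t += 1
        return q, t
    t = hit.target_span[1]
    while q < len(contig) and t > 0 and contig[q] == _COMP[target[t - 1]]:
        q += 1
        t -= 1
    return q, t


def _walk_block_start(contig: str, target: str, hit) -> tuple[int, int]:
    """Exact-extend a right-flanking hit 5' from its (unique) end anchor.

    Returns (contig position where the block starts, target start coord).
    """
    q = hit.query_span[1]
    if hit.strand == "+":
        t = hit.target_span[1]
        while q > 0 and t > 0 and contig[q - 1] == target[t - 1]:
            q -= 1
            t -= 1
        return q, t
    t = hit.target_span[0]
    while q > 0 and t < len(target) and contig[q - 1] == _COMP[target[t]]:
        q -= 1
        t += 1
    return q, t


def annotate_contigs(
    contigs: Sequence[SeqRecord],
    refs: dict[str, str],
    lib: SegmentLibrary,
    cut: int = 1000,
    min_side: int = MIN_BLOCK_SIDE,
) -> list[JunctionCall]:
    """Call junctions where two reference blocks abut or flank an insert.

    Contigs are locally aligned against the panel (genomic locus, backbone,
    template); consecutive hits of at least ``min_side`` bases along the
    contig delimit a junction, and the unaligned contig sequence between
    them is annotated against the gRNA site and the backbone.
    """
    index = SeedIndex(refs, k=15)
    calls: list[JunctionCall] = []
    for contig in contigs:
        if len(contig) < 2 * min_side:
            continue
        hits = [
            h
            for h in align_local(contig, index, min_score=30)
            if h.query_len >= min_side
        ]
        hits.sort(key=lambda h: h.query_span[0])
        for left, right in zip(hits, hits[1:]):
            q_gap = right.query_span[0] - left.query_span[1]
            if left.strand == "+":
                t_gap = right.target_span[0] - left.target_span[1]
            else:
                t_gap = left.target_span[0] - right.target_span[1]
            same_block = (
                left.target_id == right.target_id
                and left.strand == right.strand
                and abs(t_gap - q_gap) <= 20
                and t_gap >= -20
            )
            if same_block:
                continue
            # repeated sequence shared by both sides (the gRNA site ends
            # every template copy AND prefixes every footprint) makes the
            # raw alignment boundaries ambiguous: re-derive them by exact
            # walks anchored at the unique far end of each hit
            gap_lo, l_end = _walk_block_end(contig.seq, refs[left.target_id], left)
            gap_hi, r_start = _walk_block_start(contig.seq, refs[right.target_id], right)
            if gap_hi < gap_lo:  # microhomology: boundary position is arbitrary
                gap_hi = gap_lo
            insert = contig.seq[gap_lo:gap_hi]
            l_label = _block_label(left.target_id, left.strand, left.target_span, cut)
            r_label = _block_label(right.target_id, right.strand, right.target_span, cut)
            calls.append(
                JunctionCall(
                    contig_id=contig.id,
                    left=(l_label[0], l_label[1], l_end),
                    right=(r_label[0], r_label[1], r_start),
                    insert_seq=insert,
                    annotation=annotate_insert(insert, lib),
                )
            )
    return calls


def junction_table(calls: Sequence[JunctionCall]) -> pd.DataFrame:
    rows = [
        (
            c.contig_id,
            c.left[0],
            c.left[1],
            c.left[2],
            c.right[0],
            c.right[1],
            c.right[2],
            c.insert_len,
            c.insert_seq,
            c.annotation,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "left_label",
            "left_strand",
            "left_end",
            "right_label",
            "right_strand",
            "right_start",
            "insert_len",
            "insert_seq",
            "annotation",
        ],
    )
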