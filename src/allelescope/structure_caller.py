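"""Allele structure inference from tiled long-read alignments.

Candidate long reads are fragmented into 1 kb subreads with 0.5 kb overlap
and each subread is mapped to a composite reference that carries the
genomic locus, the plasmid backbone and a *single* copy of the complete
donor template.  Consecutive subread hits with the same reference label,
the same orientation and collinear coordinates are merged into blocks, so
each read becomes a short word over block symbols (e.g. ``L T+ P+ T-``).
Reads with identical canonical words form clusters; cluster words are then
chained by suffix/prefix overlap, anchored at the genomic flanks, into
maximal allele structures.  A structure is reported when it is supported by
at least ``min_reads`` reads drawn from at least ``min_clusters`` distinct
clusters.

Copy number falls out of the word itself: on the collapsed reference every
traversal of the template produces one block, so the number of template
symbols in the assembled word is the concatemer copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np

from .allele_model import SegmentLibrary
from .read_sim import ReadSet
from .seq_core import (
    AlignmentHit,
    InputError,
    SeedIndex,
    SeqRecord,
    align_local,
    revcomp,
)

Symbol = tuple[str, str]  # (block name, strand)

DEFAULT_WINDOW = 1000
DEFAULT_STEP = 500
MIN_BLOCK_LEN = 300
COLLINEAR_TOL = 200
MAX_STRUCTURE_BLOCKS = 24


@dataclass
class CompositeReference:
    """Named reference panel: locus contig, backbone, one template copy."""

    refs: dict[str, str]
    cut: int = 1000
    index: SeedIndex = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if "template" not in self.refs:
            raise InputError("composite reference requires a 'template' contig")
        self.index = SeedIndex(self.refs, k=15)

    @classmethod
    def from_library(
        cls,
        lib: SegmentLibrary,
        decoys: Optional[list[SeqRecord]] = None,
        cut: int = 1000,
    ) -> "CompositeReference":
        refs = {
            "chr17": lib["CHR17_L"].seq + lib["CHR17_R"].seq,
            "template": lib["TEMPLATE"].seq,
            "puc": lib["PUC"].seq,
        }
        for rec in decoys or []:
            refs[rec.id] = rec.seq
        return cls(refs, cut=cut)


@dataclass
class ReadBlock:
    label: str
    strand: str
    read_span: tuple[int, int]
    ref_span: tuple[int, int]
    n_subreads: int = 1


@dataclass
class BlockString:
    read_id: str
    blocks: list[ReadBlock]

    def symbols(self, ref: CompositeReference) -> tuple[Symbol, ...]:
        out = []
        cut = ref.cut
        for b in self.blocks:
            if b.label == "chr17":
                lo, hi = b.ref_span
                if lo <= cut - 50 and hi >= cut + 50:
                    out.append(("LOCUS", b.strand))
                elif hi <= cut + 50:
                    out.append(("L", b.strand))
                else:
                    out.append(("R", b.strand))
            elif b.label == "template":
                out.append(("T", b.strand))
            elif b.label == "puc":
                out.append(("P", b.strand))
            else:
                out.append((b.label, b.strand))
        return tuple(out)


def tile_read(
    read: SeqRecord, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> list[tuple[int, SeqRecord]]:
    """Overlapping subreads starting every ``step`` bases.

    The trailing fragment is merged into the final window so every subread
    is at least ``window - step`` long.
    """
    if not window > step > 0:
        raise InputError("require window > step > 0")
    n = len(read)
    if n == 0:
        return []
    if n <= window:
        return [(0, SeqRecord(f"{read.id}|0", read.seq))]
    count = int(np.ceil((n - window) / step)) + 1
    out = []
    for i in range(count):
        start = i * step
        end = min(n, start + window) if i < count - 1 else n
        out.append((start, SeqRecord(f"{read.id}|{start}", read.seq[start:end])))
    return out


def map_subreads(
    subreads: list[tuple[int, SeqRecord]],
    ref: CompositeReference,
    min_hit_len: int = 300,
    min_identity: float = 0.7,
) -> list[tuple[int, Optional[AlignmentHit]]]:
    """Best hit per subread, or None when nothing passes the threshold.

    Ties are broken deterministically: higher score, then lexicographically
    smaller reference label, then leftmost target start.
    """
    out = []
    for start, sub in subreads:
        hits = align_local(sub, ref.index, min_score=100)
        best = None
        for h in hits:
            if h.query_len < min_hit_len or h.identity < min_identity:
                continue
            key = (-h.score, h.target_id, h.target_span[0])
            if best is None or key < (-best.score, best.target_id, best.target_span[0]):
                best = h
        out.append((start, best))
    return out


def block_string(
    read: SeqRecord,
    subread_hits: list[tuple[int, Optional[AlignmentHit]]],
    min_block_len: int = MIN_BLOCK_LEN,
    collinear_tol: int = COLLINEAR_TOL,
) -> BlockString:
    """Merge collinear subread hits into maximal blocks.

    Two consecutive hits extend the same block when they agree in reference
    label and orientation and their reference coordinates advance with the
    read (within ``collinear_tol``); anything else - an orientation flip, a
    label change, or a coordinate reset at a tandem-copy boundary - starts a
    new block.
    """
    blocks: list[ReadBlock] = []
    for sub_start, hit in sorted(subread_hits, key=lambda x: x[0]):
        if hit is None:
            continue
        q_lo = sub_start + hit.query_span[0]
        q_hi = sub_start + hit.query_span[1]
        t_lo, t_hi = hit.target_span
        cur = blocks[-1] if blocks else None
        merged = False
        if cur is not None and cur.label == hit.target_id and cur.strand == hit.strand:
            d_read = q_lo - cur.read_span[0]
            if hit.strand == "+":
                d_ref = t_lo - cur.ref_span[0]
            else:
                d_ref = cur.ref_span[1] - t_hi
            # small negative d_ref is subread-overlap jitter; a tandem-copy
            # restart shows up as a large diagonal break and is never merged
            if (
                abs(d_ref - d_read) <= collinear_tol + 0.02 * abs(d_read)
                and d_ref >= -collinear_tol
            ):
                cur.read_span = (cur.read_span[0], max(cur.read_span[1], q_hi))
                cur.ref_span = (
                    min(cur.ref_span[0], t_lo),
                    max(cur.ref_span[1], t_hi),
                )
                cur.n_subreads += 1
                merged = True
        if not merged:
            blocks.append(
                ReadBlock(hit.target_id, hit.strand, (q_lo, q_hi), (t_lo, t_hi))
            )
    kept = [b for b in blocks if b.read_span[1] - b.read_span[0] >= min_block_len]
    # clip the small overlaps introduced by subread overlap
    for prev, nxt in zip(kept, kept[1:]):
        if nxt.read_span[0] < prev.read_span[1]:
            nxt.read_span = (prev.read_span[1], max(nxt.read_span[1], prev.read_span[1]))
    return BlockString(read.id, kept)


# ---------------------------------------------------------------------------
# clustering and canonicalisation
# ---------------------------------------------------------------------------


def rc_symbols(word: tuple[Symbol, ...]) -> tuple[Symbol, ...]:
    flip = {"+": "-", "-": "+"}
    return tuple((name, flip[strand]) for name, strand in reversed(word))


def canonical(word: tuple[Symbol, ...]) -> tuple[Symbol, ...]:
    if not word:
        return word
    rc = rc_symbols(word)
    return min(word, rc)


@dataclass
class Cluster:
    cluster_id: int
    word: tuple[Symbol, ...]
    read_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.read_ids)


def cluster_blockstrings(
    words: dict[str, tuple[Symbol, ...]],
) -> list[Cluster]:
    """Group reads by identical canonical block words."""
    groups: dict[tuple[Symbol, ...], list[str]] = {}
    for rid, word in words.items():
        if not word:
            continue
        groups.setdefault(canonical(word), []).append(rid)
    clusters = []
    for i, key in enumerate(sorted(groups)):
        clusters.append(Cluster(i, key, sorted(groups[key])))
    return clusters


# ---------------------------------------------------------------------------
# structure assembly
# ---------------------------------------------------------------------------


@dataclass
class StructureCall:
    name: str
    word: tuple[Symbol, ...]
    n_template_copies: int
    n_backbone_copies: int
    insertion_length_bp: int
    support_read_ids: list[str]
    cluster_ids: list[int]
    ambiguous: bool = False
    cutsite_indel: Optional[int] = None
    cutsite_insert_seq: str = ""

    @property
    def n_support(self) -> int:
        return len(self.support_read_ids)

    @property
    def insertion_length_kb(self) -> int:
        return self.insertion_length_bp // 1000


def _is_sub(word: tuple, full: tuple) -> bool:
    n, m = len(word), len(full)
    if n > m:
        return False
    return any(full[i : i + n] == word for i in range(m - n + 1))


def _overlap(a: tuple, b: tuple) -> int:
    """Longest proper suffix of ``a`` that is a prefix of ``b``."""
    best = 0
    for o in range(1, min(len(a), len(b) - 1) + 1):
        if a[-o:] == b[:o]:
            best = o
    return best


L_SYM = ("L", "+")
R_SYM = ("R", "+")
LOCUS_SYM = ("LOCUS", "+")


def _assemble_words(
    cluster_words: list[tuple[Symbol, ...]],
    max_blocks: int = MAX_STRUCTURE_BLOCKS,
) -> list[tuple[Symbol, ...]]:
    """Chain cluster words into maximal flank-anchored structures.

    Extensions branch over every word overlapping the current suffix by at
    least three symbols; two-symbol overlaps are used only when no longer
    overlap exists.  A chain is complete when it runs from the left genomic
    flank to the right one.
    """
    pool = set()
    for w in cluster_words:
        pool.add(w)
        pool.add(rc_symbols(w))
    seeds = [w for w in pool if w and w[0] == L_SYM]
    complete: set[tuple[Symbol, ...]] = set()
    seen: set[tuple[Symbol, ...]] = set()
    stack = list(seeds)
    while stack:
        s = stack.pop()
        if s in seen:
            continue
        seen.add(s)
        if s[-1] == R_SYM:
            complete.add(s)
            continue
        if len(s) >= max_blocks:
            continue
        ext3, ext2 = [], []
        for t in pool:
            o = _overlap(s, t)
            if o >= 3:
                ext3.append(s + t[o:])
            elif o == 2:
                ext2.append(s + t[o:])
        for nxt in ext3 if ext3 else ext2:
            stack.append(nxt)
    # drop complete words that embed another complete word (chimera guard)
    out = []
    for w in sorted(complete):
        if any(v != w and _is_sub(v, w) for v in complete):
            continue
        out.append(w)
    return out


def call_structures(
    clusters: list[Cluster],
    ref: CompositeReference,
    min_reads: int = 2,
    min_clusters: int = 2,
    per_cluster_min: int = 1,
) -> list[StructureCall]:
    """Report allele structures meeting the read/cluster support rule.

    ``per_cluster_min`` configures the stricter reading of the support rule
    (every counted cluster must contribute at least this many reads).
    """
    if min_reads < 1 or min_clusters < 1:
        raise InputError("support thresholds must be >= 1")
    words = [c.word for c in clusters]
    assembled = _assemble_words(words)
    # the wild-type / small-indel allele shows up as a single locus block
    if any(c.word == (LOCUS_SYM,) for c in clusters):
        assembled.append((LOCUS_SYM,))
    calls = []
    support_map: dict[tuple, set[str]] = {}
    cluster_map: dict[tuple, list[int]] = {}
    for word in assembled:
        supp: set[str] = set()
        cids: list[int] = []
        for c in clusters:
            if _is_sub(c.word, word) or _is_sub(rc_symbols(c.word), word):
                n_ok = c.size >= per_cluster_min
                if n_ok:
                    supp.update(c.read_ids)
                    cids.append(c.cluster_id)
        support_map[word] = supp
        cluster_map[word] = cids
    # reads whose whole word equals the structure word span the entire
    # allele and corroborate it on their own; partial words instead need
    # agreement across more than one cluster
    full_span = {
        w: sum(c.size for c in clusters if c.word == canonical(w)) for w in assembled
    }
    kept_words = [
        w
        for w in assembled
        if (len(support_map[w]) >= min_reads and len(cluster_map[w]) >= min_clusters)
        or full_span[w] >= min_reads
    ]
    tlen = len(ref.refs["template"])
    plen = len(ref.refs.get("puc", ""))
    for word in kept_words:
        n_t = sum(1 for s in word if s[0] == "T")
        n_p = sum(1 for s in word if s[0] == "P")
        ins_len = n_t * tlen + n_p * plen
        calls.append(
            StructureCall(
                name="",
                word=word,
                n_template_copies=n_t,
                n_backbone_copies=n_p,
                insertion_length_bp=ins_len,
                support_read_ids=sorted(support_map[word]),
                cluster_ids=sorted(cluster_map[word]),
            )
        )
    # ambiguity: no read word pins this structure uniquely among the calls
    for call in calls:
        unique = False
        for c in clusters:
            if c.word and (
                _is_sub(c.word, call.word) or _is_sub(rc_symbols(c.word), call.word)
            ):
                others = [
                    o
                    for o in calls
                    if o is not call
                    and (
                        _is_sub(c.word, o.word)
                        or _is_sub(rc_symbols(c.word), o.word)
                    )
                ]
                if not others:
                    unique = True
                    break
        call.ambiguous = not unique
    calls.sort(key=lambda c: -c.insertion_length_bp)
    for i, call in enumerate(calls):
        call.name = f"structure_{i + 1}"
    return calls


# ---------------------------------------------------------------------------
# cut-site indel refinement for template-free structures
# ---------------------------------------------------------------------------


def call_cutsite_indel(
    structure: StructureCall,
    ref: CompositeReference,
    reads_by_id: dict[str, SeqRecord],
    anchor_len: int = 200,
    anchor_offset: int = 30,
    max_reads: int = 60,
) -> tuple[int, str]:
    """Signed indel length (and inserted sequence) at the Cas9 cut site.

    Two wild-type anchors flanking the cut (offset so small deletions do not
    erode them) are located in every supporting read; the distance between
    their images, minus the wild-type distance, is the per-read indel
    estimate.  The call is the median across reads; the inserted sequence is
    the modal read subsequence between the anchor images.
    """
    if structure.n_template_copies != 0:
        raise InputError("cut-site indel is defined for template-free structures")
    locus = ref.refs["chr17"]
    cut = ref.cut
    a_left = locus[cut - anchor_offset - anchor_len : cut - anchor_offset]
    a_right = locus[cut + anchor_offset : cut + anchor_offset + anchor_len]
    wt_gap = 2 * anchor_offset
    deltas = []
    inserts = []
    for rid in structure.support_read_ids[:max_reads]:
        rec = reads_by_id.get(rid)
        if rec is None:
            continue
        best = None
        for seq in (rec.seq, revcomp(rec.seq)):
            rl = edlib.align(a_left, seq, mode="HW", task="locations")
            rr = edlib.align(a_right, seq, mode="HW", task="locations")
            if rl["editDistance"] < 0 or rr["editDistance"] < 0:
                continue
            if not rl["locations"] or not rr["locations"]:
                continue
            e1 = rl["locations"][0][1] + 1
            s2 = rr["locations"][0][0]
            cost = rl["editDistance"] + rr["editDistance"]
            if s2 - e1 < -wt_gap - 100 or s2 - e1 > 20000:
                continue
            if best is None or cost < best[0]:
                best = (cost, e1, s2, seq)
        if best is None:
            continue
        _, e1, s2, seq = best
        delta = (s2 - e1) - wt_gap
        deltas.append(delta)
        if delta > 0:
            lo = e1 + anchor_offset
            hi = lo + delta
            if 0 <= lo <= hi <= len(seq):
                inserts.append(seq[lo:hi])
    if not deltas:
        return 0, ""
    indel = int(np.median(deltas))
    seq_out = ""
    if indel > 0 and inserts:
        right_len = [s for s in inserts if len(s) == indel]
        pool = right_len or inserts
        vals, counts = np.unique(pool, return_counts=True)
        seq_out = str(vals[np.argmax(counts)])
    return indel, seq_out


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------


def blockstrings_for_reads(
    reads: ReadSet,
    ref: CompositeReference,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_block_len: int = MIN_BLOCK_LEN,
) -> dict[str, tuple[Symbol, ...]]:
    """Tile, map and symbolise every read; returns read_id -> block word."""
    words = {}
    for read in reads.reads:
        subs = tile_read(read, window, step)
        hits = map_subreads(subs, ref)
        bs = block_string(read, hits, min_block_len=min_block_len)
        words[read.id] = bs.symbols(ref)
    return words
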