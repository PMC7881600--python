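"""Sequence primitives shared by every stage of the pipeline.

This module keeps the on-disk formats (FASTA, FASTQ, BED) and the in-memory
records deliberately small: a read or reference is a :class:`SeqRecord`, a
pairwise match is an :class:`AlignmentHit` with 0-based half-open spans on
the forward strand of the target.

The local aligner follows the usual seed-chain-extend recipe: exact seed
words are located on both strands, chained by diagonal, and each chained
region is polished with an edit-distance alignment (edlib).  Scores use the
classic unit scheme match +1 / mismatch -1 / gap open -2 / gap extend -1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# unit scoring scheme; all thresholds in the package are expressed in it
MATCH = 1
MISMATCH = -1
GAP_OPEN = -2
GAP_EXTEND = -1


class InputError(ValueError):
    """Raised when an operation receives out-of-contract input."""


class ParseError(ValueError):
    """Raised on malformed FASTA/FASTQ input; message names the line."""


@dataclass
class SeqRecord:
    """A named DNA sequence with optional per-base Phred qualities."""

    id: str
    seq: str
    qual: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("record id must be non-empty")
        self.seq = self.seq.upper()
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise InputError(f"non-DNA characters in {self.id!r}: {sorted(bad)}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise InputError(
                f"quality length {len(self.qual)} != sequence length "
                f"{len(self.seq)} for {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, id_suffix: str = "") -> "SeqRecord":
        qual = None if self.qual is None else list(self.qual)[::-1]
        return SeqRecord(self.id + id_suffix, revcomp(self.seq), qual)


@dataclass
class AlignmentHit:
    """A local alignment of a query against the forward strand of a target.

    ``strand`` is the strand of the query that matched; spans are always
    reported in forward-strand coordinates of both sequences.
    """

    query_id: str
    target_id: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    strand: str
    identity: float
    score: float
    cigar: str = ""

    @property
    def query_len(self) -> int:
        return self.query_span[1] - self.query_span[0]

    @property
    def target_len(self) -> int:
        return self.target_span[1] - self.target_span[0]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise InputError(f"non-DNA characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def kmers(seq: str, k: int) -> list[str]:
    """All overlapping k-mers of ``seq`` in order (empty if seq shorter)."""
    if k <= 0:
        raise InputError(f"k must be positive, got {k}")
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Sanger Phred+33)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly multi-line) FASTA file."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(SeqRecord(rec.id, str(rec.seq).upper()))
    except ValueError as exc:  # malformed input
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Strict 4-line FASTQ reader; errors name the offending line number."""
    records = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ParseError(f"{path}: truncated FASTQ, {len(lines)} lines (line {len(lines)})")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ParseError(f"{path}: line {i + 1}: header must start with '@'")
        if not plus.startswith("+"):
            raise ParseError(f"{path}: line {i + 3}: separator must start with '+'")
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}: line {i + 4}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        phred = [ord(c) - 33 for c in qual]
        if phred and (min(phred) < 0 or max(phred) > 93):
            raise ParseError(f"{path}: line {i + 4}: quality out of Phred+33 range")
        records.append(SeqRecord(head[1:].split()[0], seq, phred))
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            qual = r.qual if r.qual is not None else [30] * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{''.join(chr(q + 33) for q in qual)}\n")


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write BED6 rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for row in intervals:
            chrom, start, end, name, score, strand = row
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# local alignment: seed -> chain -> edlib-polish
# ---------------------------------------------------------------------------

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_stats(cigar: str) -> tuple[int, int, int, int, float]:
    """Return (matches, mismatches, gap_bases, columns, score)."""
    matches = mismatches = gap_bases = gaps = 0
    for n, op in _CIG_RE.findall(cigar):
        n = int(n)
        if op == "=":
            matches += n
        elif op in "XM":
            mismatches += n
        else:
            gap_bases += n
            gaps += 1
    cols = matches + mismatches + gap_bases
    score = (
        MATCH * matches
        + MISMATCH * mismatches
        + gaps * (GAP_OPEN - GAP_EXTEND)
        + gap_bases * GAP_EXTEND
    )
    return matches, mismatches, gap_bases, cols, score


class SeedIndex:
    """Exact k-mer position index over a set of named target sequences."""

    def __init__(self, targets: dict[str, str], k: int = 15):
        self.k = k
        self.targets = targets
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in targets.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((name, i))

    def seeds(self, seq: str) -> dict[str, list[tuple[int, int]]]:
        """Map target name -> [(query_pos, target_pos), ...]."""
        out: dict[str, list[tuple[int, int]]] = {}
        k = self.k
        idx = self.index
        for qpos in range(len(seq) - k + 1):
            hits = idx.get(seq[qpos : qpos + k])
            if hits:
                for name, tpos in hits:
                    out.setdefault(name, []).append((qpos, tpos))
        return out


def _chain_seeds(
    seeds: list[tuple[int, int]], diag_tol: int = 120, max_gap: int = 1200
) -> list[tuple[int, int, int, int, int]]:
    """Cluster seed matches into candidate regions by diagonal.

    Returns (qstart, qend, tstart, tend, n_seeds) per cluster (ends are
    seed start positions; the caller pads by k).
    """
    if not seeds:
        return []
    seeds = sorted(seeds, key=lambda s: (s[0] - s[1], s[1]))
    clusters = []
    cur = [seeds[0]]
    for s in seeds[1:]:
        prev = cur[-1]
        if abs((s[0] - s[1]) - (prev[0] - prev[1])) <= diag_tol and (
            s[1] - prev[1] <= max_gap
        ):
            cur.append(s)
        else:
            clusters.append(cur)
            cur = [s]
    clusters.append(cur)
    out = []
    for cl in clusters:
        qs = min(q for q, _ in cl)
        qe = max(q for q, _ in cl)
        ts = min(t for _, t in cl)
        te = max(t for _, t in cl)
        out.append((qs, qe, ts, te, len(cl)))
    return out


def _merge_clusters(
    clusters: list[tuple[int, int, int, int, int]], join_gap: int = 400
) -> list[tuple[int, int, int, int, int]]:
    """Join colinear clusters separated by small gaps (indel-rich regions)."""
    if not clusters:
        return []
    clusters = sorted(clusters, key=lambda c: c[0])
    merged = [clusters[0]]
    for c in clusters[1:]:
        p = merged[-1]
        diag_p = p[0] - p[2]
        diag_c = c[0] - c[2]
        if (
            c[0] - p[1] <= join_gap
            and c[2] >= p[2]
            and abs(diag_c - diag_p) <= join_gap
        ):
            merged[-1] = (p[0], max(p[1], c[1]), p[2], max(p[3], c[3]), p[4] + c[4])
        else:
            merged.append(c)
    return merged


def _trim_to_local(cigar: str) -> tuple[int, int, int, int, list[tuple[int, str]]]:
    """Best-scoring contiguous run of cigar operations (Kadane on runs).

    A global alignment of two seed-chained windows can carry unaligned
    overhangs at either end (e.g. novel junction sequence); trimming to the
    maximum-scoring run turns it into a proper local hit.  Returns the
    query/target bases trimmed at the head and tail plus the kept runs.
    """
    runs = [(int(n), op) for n, op in _CIG_RE.findall(cigar)]

    def run_score(n: int, op: str) -> int:
        if op == "=":
            return MATCH * n
        if op in "XM":
            return MISMATCH * n
        return GAP_OPEN + GAP_EXTEND * (n - 1)

    best = (0, 0, 0)  # score, start_run, end_run (half-open)
    cur_score = 0
    cur_start = 0
    for i, (n, op) in enumerate(runs):
        s = run_score(n, op)
        if cur_score <= 0:
            cur_score = s
            cur_start = i
        else:
            cur_score += s
        if cur_score > best[0]:
            best = (cur_score, cur_start, i + 1)
    _, lo, hi = best
    head_q = head_t = tail_q = tail_t = 0
    for n, op in runs[:lo]:
        if op in "=XM":
            head_q += n
            head_t += n
        elif op == "I":
            head_q += n
        else:
            head_t += n
    for n, op in runs[hi:]:
        if op in "=XM":
            tail_q += n
            tail_t += n
        elif op == "I":
            tail_q += n
        else:
            tail_t += n
    return head_q, head_t, tail_q, tail_t, runs[lo:hi]


def _polish(
    query: str,
    target: str,
    qid: str,
    tid: str,
    region: tuple[int, int, int, int, int],
    k: int,
    strand: str,
) -> Optional[AlignmentHit]:
    qs, qe, ts, te, _ = region
    qe += k
    te += k
    sub_q = query[qs:qe]
    sub_t = target[ts:te]
    if not sub_q or not sub_t:
        return None
    res = edlib.align(sub_q, sub_t, task="path", mode="NW")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    head_q, head_t, tail_q, tail_t, runs = _trim_to_local(res["cigar"])
    if not runs:
        return None
    cigar = "".join(f"{n}{op}" for n, op in runs)
    matches, _, _, cols, score = _cigar_stats(cigar)
    if cols == 0:
        return None
    identity = matches / cols
    qs += head_q
    qe -= tail_q
    ts += head_t
    te -= tail_t
    if qe <= qs or te <= ts:
        return None
    q_span = (qs, qe)
    if strand == "-":
        n = len(query)
        q_span = (n - qe, n - qs)
    return AlignmentHit(
        query_id=qid,
        target_id=tid,
        query_span=q_span,
        target_span=(ts, te),
        strand=strand,
        identity=identity,
        score=float(score),
        cigar=cigar,
    )


def align_local(
    query: SeqRecord,
    target: SeqRecord | SeedIndex,
    min_score: float = 50.0,
    seed_k: int = 15,
    min_seeds: int = 2,
) -> list[AlignmentHit]:
    """All non-overlapping local hits of ``query`` on both strands.

    ``target`` may be a single record or a prebuilt :class:`SeedIndex` over
    several references (the index is reused across many queries).  Hits are
    sorted by decreasing score; overlapping lower-scoring hits on the query
    are suppressed.
    """
    if len(query) == 0:
        raise InputError("empty query")
    if isinstance(target, SeedIndex):
        index = target
    else:
        if len(target) == 0:
            raise InputError("empty target")
        index = SeedIndex({target.id: target.seq}, k=seed_k)
    k = index.k
    hits: list[AlignmentHit] = []
    fwd = query.seq
    rev = revcomp(fwd)
    for strand, qseq in (("+", fwd), ("-", rev)):
        per_target = index.seeds(qseq)
        for tname, seed_list in per_target.items():
            regions = _merge_clusters(_chain_seeds(seed_list))
            for region in regions:
                if region[4] < min_seeds:
                    continue
                hit = _polish(qseq, index.targets[tname], query.id, tname, region, k, strand)
                if hit is not None and hit.score >= min_score:
                    hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.target_id, h.target_span[0], h.strand))
    kept: list[AlignmentHit] = []
    for h in hits:
        ok = True
        for other in kept:
            lo = max(h.query_span[0], other.query_span[0])
            hi = min(h.query_span[1], other.query_span[1])
            ov = hi - lo
            if ov > min(50, 0.5 * min(h.query_len, other.query_len)):
                ok = False
                break
        if ok:
            kept.append(h)
    return kept


def align_global_identity(a: str, b: str) -> float:
    """End-to-end identity between two sequences (matches / columns)."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="path", mode="NW")
    matches, _, _, cols, _ = _cigar_stats(res["cigar"])
    return matches / cols if cols else 0.0
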