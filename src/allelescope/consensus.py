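"""Confirmation of allele substructures by multiple alignment + consensus.

No single long read spans the 38 kb concatemer, so its sequence is
confirmed piecewise: reads whose block words place them uniquely on a
called structure are grouped per junction-centred substructure, trimmed of
excess wild-type flank, aligned with a centre-star multiple sequence
alignment, and collapsed to a majority-rule consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .seq_core import (
    InputError,
    SeqRecord,
    _CIG_RE,
    align_global_identity,
    revcomp,
)
from .structure_caller import (
    BlockString,
    CompositeReference,
    StructureCall,
    Symbol,
    rc_symbols,
)

import edlib

FLANK_MARGIN = 200


@dataclass
class SubstructureGroup:
    """Reads covering one junction of a called structure, trimmed to it."""

    substructure_id: str
    structure_name: str
    junction_index: int  # between word position j and j+1
    segments: list[tuple[str, str]]  # (read_id, trimmed sequence)

    @property
    def n_reads(self) -> int:
        return len(self.segments)


def _placements(word: tuple, target: tuple) -> list[tuple[int, bool]]:
    """Offsets at which ``word`` (or its rc) occurs in ``target``."""
    out = []
    n, m = len(word), len(target)
    rc = rc_symbols(word)
    for i in range(m - n + 1):
        win = target[i : i + n]
        if win == word:
            out.append((i, False))
        if win == rc and rc != word:
            out.append((i, True))
    return out


def group_and_trim(
    blockstrings: dict[str, BlockString],
    words: dict[str, tuple[Symbol, ...]],
    structures: Sequence[StructureCall],
    reads_by_id: dict[str, SeqRecord],
    ref: CompositeReference,
    flank_margin: int = FLANK_MARGIN,
    min_word_len: int = 2,
) -> list[SubstructureGroup]:
    """Assign uniquely placeable reads to junction substructures.

    A read contributes to junction ``j`` of a structure when its block word
    has exactly one placement on the structure word (counting both
    orientations) and that placement covers positions ``j`` and ``j+1``.
    The contributed segment runs from the start of the left block to the end
    of the right block, with genomic flank blocks clipped to
    ``flank_margin`` bases from the junction.
    """
    groups: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for rid, word in words.items():
        if len(word) < min_word_len:
            continue
        bs = blockstrings.get(rid)
        rec = reads_by_id.get(rid)
        if bs is None or rec is None or len(bs.blocks) != len(word):
            continue
        for st in structures:
            if len(st.word) < 2:
                continue
            pls = _placements(word, st.word)
            if len(pls) != 1:
                continue
            offset, flipped = pls[0]
            # orient the read along the structure
            if flipped:
                n = len(rec.seq)
                blocks = list(reversed(bs.blocks))
                spans = [(n - b.read_span[1], n - b.read_span[0]) for b in blocks]
                seq = revcomp(rec.seq)
                labels = [s[0] for s in rc_symbols(word)]
            else:
                blocks = bs.blocks
                spans = [b.read_span for b in blocks]
                seq = rec.seq
                labels = [s[0] for s in word]
            for local_j in range(len(word) - 1):
                j = offset + local_j
                a = spans[local_j][0]
                b_end = spans[local_j + 1][1]
                boundary = spans[local_j][1]
                if labels[local_j] in ("L", "R", "LOCUS"):
                    a = max(a, boundary - flank_margin)
                if labels[local_j + 1] in ("L", "R", "LOCUS"):
                    b_end = min(b_end, spans[local_j + 1][0] + flank_margin)
                if b_end - a < 100:
                    continue
                groups.setdefault((st.name, j), []).append((rid, seq[a:b_end]))
    out = []
    for (name, j), segs in sorted(groups.items()):
        out.append(
            SubstructureGroup(
                substructure_id=f"{name}:junction_{j}",
                structure_name=name,
                junction_index=j,
                segments=sorted(segs),
            )
        )
    return out


# ---------------------------------------------------------------------------
# centre-star MSA
# ---------------------------------------------------------------------------


def _pairwise_runs(query: str, center: str) -> list[tuple[int, str]]:
    res = edlib.align(query, center, task="path", mode="NW")
    return [(int(n), op) for n, op in _CIG_RE.findall(res["cigar"])]


def msa(seqs: Sequence[str], max_seqs: int = 30) -> list[str]:
    """Centre-star multiple alignment ("once a gap, always a gap").

    The centre is the sequence with the highest summed pairwise identity
    (computed on at most ``max_seqs`` sequences; larger groups are
    subsampled deterministically by taking the first ``max_seqs`` after
    sorting).  Every other sequence is pairwise aligned to the centre and
    the gaps are merged column-wise.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise InputError("MSA needs at least two sequences")
    if len(seqs) > max_seqs:
        seqs = sorted(seqs, key=len, reverse=True)[:max_seqs]
    sums = np.zeros(len(seqs))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ident = align_global_identity(seqs[i], seqs[j])
            sums[i] += ident
            sums[j] += ident
    center_idx = int(np.argmax(sums))
    center = seqs[center_idx]
    others = [s for i, s in enumerate(seqs) if i != center_idx]
    aligns = [_pairwise_runs(s, center) for s in others]
    # per-alignment insertions before each center position (and at the end)
    ins_profiles = []
    for runs in aligns:
        ins = np.zeros(len(center) + 1, dtype=int)
        cpos = 0
        for n, op in runs:
            if op in "=XM":
                cpos += n
            elif op == "D":  # gap in query, consumes center
                cpos += n
            else:  # I: insertion in query before center position cpos
                ins[cpos] += n
        ins_profiles.append(ins)
    master = np.zeros(len(center) + 1, dtype=int)
    for ins in ins_profiles:
        master = np.maximum(master, ins)

    def render(seq: str, runs: Optional[list[tuple[int, str]]]) -> str:
        cols = []
        if runs is None:  # the center itself
            for p, ch in enumerate(center):
                cols.append("-" * master[p])
                cols.append(ch)
            cols.append("-" * master[len(center)])
            return "".join(cols)
        qpos = 0
        cpos = 0
        pending_ins = ""
        for n, op in runs:
            if op == "I":
                pending_ins += seq[qpos : qpos + n]
                qpos += n
                continue
            for _ in range(n):
                cols.append(pending_ins + "-" * (master[cpos] - len(pending_ins)))
                pending_ins = ""
                if op in "=XM":
                    cols.append(seq[qpos])
                    qpos += 1
                else:  # D
                    cols.append("-")
                cpos += 1
        cols.append(pending_ins + "-" * (master[len(center)] - len(pending_ins)))
        return "".join(cols)

    rows = []
    oi = 0
    for i in range(len(seqs)):
        if i == center_idx:
            rows.append(render(center, None))
        else:
            rows.append(render(others[oi], aligns[oi]))
            oi += 1
    assert len({len(r) for r in rows}) == 1
    return rows


def consensus_call(rows: Sequence[str], plurality: float = 0.5) -> SeqRecord:
    """Majority-rule column consensus of an alignment matrix.

    Gap-majority columns emit nothing; otherwise the most frequent residue
    is emitted when its frequency among non-gap entries exceeds the
    plurality, with ties broken by the fixed base order A < C < G < T.
    """
    if not rows:
        raise InputError("empty alignment")
    mat = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)
    out = []
    for col in mat.T:
        residues = col[col != b"-"]
        n_gap = col.size - residues.size
        if residues.size == 0 or n_gap > residues.size:
            continue
        vals, counts = np.unique(residues, return_counts=True)
        top = counts.max()
        tied = sorted(v.decode() for v, c in zip(vals, counts) if c == top)
        if len(tied) > 1 or top / residues.size > plurality:
            out.append(tied[0])
    return SeqRecord("consensus", "".join(out))


def consensus_for_group(
    group: SubstructureGroup, plurality: float = 0.5
) -> Optional[SeqRecord]:
    if group.n_reads < 2:
        return None
    rows = msa([s for _, s in group.segments])
    rec = consensus_call(rows, plurality)
    rec.id = f"{group.substructure_id}_consensus"
    return rec
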