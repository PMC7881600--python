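"""Candidate long-read recruitment against a small bait reference set.

Before any structure inference, long reads are screened against four baits:
the wild-type locus (1 kb either side of the cut), the plasmid backbone,
the complete donor template, and the small NHEJ-insertion allele.  A read
is recruited if it carries at least one sufficiently long, sufficiently
identical local hit to any bait on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .allele_model import AlleleBlueprint, SegmentLibrary, build_allele
from .read_sim import ReadSet
from .seq_core import AlignmentHit, InputError, SeedIndex, SeqRecord, align_local, write_fasta

DEFAULT_MIN_HIT_LEN = 500
DEFAULT_MIN_IDENTITY = 0.8


@dataclass
class BaitSet:
    """The four bait sequences used to fish candidate reads."""

    wildtype_locus: SeqRecord
    backbone: SeqRecord
    complete_template: SeqRecord
    nhej_allele: SeqRecord

    def records(self) -> list[SeqRecord]:
        return [
            self.wildtype_locus,
            self.backbone,
            self.complete_template,
            self.nhej_allele,
        ]

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(self.records(), path)


def build_baits(
    lib: SegmentLibrary, blueprints: dict[str, AlleleBlueprint]
) -> BaitSet:
    """Assemble the bait set from the segment library and blueprints."""
    for need in ("wildtype", "alleleA"):
        if need not in blueprints:
            raise InputError(f"blueprint {need!r} required to build baits")
    wt = build_allele(lib, blueprints["wildtype"]).record
    nhej = build_allele(lib, blueprints["alleleA"]).record
    return BaitSet(
        wildtype_locus=SeqRecord("bait_wildtype_locus", wt.seq),
        backbone=SeqRecord("bait_backbone", lib["PUC"].seq),
        complete_template=SeqRecord("bait_complete_template", lib["TEMPLATE"].seq),
        nhej_allele=SeqRecord("bait_nhej_allele", nhej.seq),
    )


def recruit_reads(
    reads: ReadSet,
    baits: BaitSet,
    min_hit_len: int = DEFAULT_MIN_HIT_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[ReadSet, pd.DataFrame]:
    """Recruit reads with a qualifying local hit to any bait.

    Returns the recruited subset (truth table filtered accordingly) and a
    per-read report of the best hit against each bait it matched.
    """
    if min_hit_len <= 0 or min_identity <= 0:
        raise InputError("recruitment thresholds must be positive")
    index = SeedIndex({r.id: r.seq for r in baits.records()}, k=15)
    kept = []
    rows = []
    for read in reads.reads:
        hits = align_local(read, index, min_score=min(100, min_hit_len // 2))
        best_per_bait: dict[str, AlignmentHit] = {}
        recruited = False
        for h in hits:
            if h.query_len >= min_hit_len and h.identity >= min_identity:
                recruited = True
            prev = best_per_bait.get(h.target_id)
            if prev is None or h.score > prev.score:
                best_per_bait[h.target_id] = h
        if recruited:
            kept.append(read)
            for bait_id, h in sorted(best_per_bait.items()):
                rows.append(
                    (
                        read.id,
                        bait_id,
                        h.query_span[0],
                        h.query_span[1],
                        h.target_span[0],
                        h.target_span[1],
                        h.strand,
                        round(h.identity, 4),
                        h.score,
                    )
                )
    report = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "bait_id",
            "q_start",
            "q_end",
            "t_start",
            "t_end",
            "strand",
            "identity",
            "score",
        ],
    )
    kept_ids = {r.id for r in kept}
    truth = reads.truth[reads.truth.read_id.isin(kept_ids)].reset_index(drop=True)
    return ReadSet(kept, truth), report
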