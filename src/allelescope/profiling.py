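"""Short-read depth profiling, off-target scanning, read-set statistics and
in-silico PCR genotyping.

These are the bookkeeping analyses around the structure calls: per-base
coverage over a small reference panel (the samtools-depth view of the
edited locus), a genome-wide check that donor sequence occurs nowhere but
the target locus, summary statistics of a read set, and predicted PCR
product sizes for a diagnostic primer pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .allele_model import SegmentLibrary, _kmer_set
from .seq_core import InputError, SeedIndex, SeqRecord, align_local, revcomp


@dataclass
class DepthProfile:
    ref_id: str
    depth: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0

    @property
    def median(self) -> float:
        return float(np.median(self.depth)) if self.depth.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ref": self.ref_id,
                "pos": np.arange(self.depth.size),
                "depth": self.depth,
            }
        )


def depth_profile(
    reads: Sequence[SeqRecord], panel: dict[str, str], min_score: float = 40.0
) -> dict[str, DepthProfile]:
    """Per-base depth after assigning each read to its best panel reference.

    Each read contributes its best local hit only (no multi-mapping split);
    the summed depth therefore equals the summed aligned target span
    lengths, a conservation property the tests rely on.
    """
    if not panel:
        raise InputError("reference panel is empty")
    index = SeedIndex(panel, k=15)
    profiles = {name: np.zeros(len(seq), dtype=np.int64) for name, seq in panel.items()}
    for read in reads:
        hits = align_local(read, index, min_score=min_score)
        if not hits:
            continue
        best = hits[0]
        lo, hi = best.target_span
        profiles[best.target_id][lo:hi] += 1
    return {name: DepthProfile(name, arr) for name, arr in profiles.items()}


def off_target_scan(
    reads: Sequence[SeqRecord],
    panel: dict[str, str],
    lib: SegmentLibrary,
    decoy_prefix: str = "decoy",
    min_score: float = 40.0,
) -> pd.DataFrame:
    """Reads that best-align away from the locus yet carry donor sequence.

    A read is flagged when its best alignment lands on a decoy contig and
    it contains any 25-mer of the donor template or backbone (either
    strand).  On a clean simulation the expected result is an empty table.
    """
    donor = _kmer_set(lib["TEMPLATE"].seq, 25) | _kmer_set(lib["PUC"].seq, 25)
    index = SeedIndex(panel, k=15)
    rows = []
    for read in reads:
        hits = align_local(read, index, min_score=min_score)
        if not hits or not hits[0].target_id.startswith(decoy_prefix):
            continue
        seq = read.seq
        carries = any(
            seq[i : i + 25] in donor for i in range(len(seq) - 24)
        )
        if carries:
            rows.append((read.id, hits[0].target_id, hits[0].target_span[0]))
    return pd.DataFrame(rows, columns=["read_id", "contig", "pos"])


def readset_stats(
    reads: Sequence[SeqRecord], genome_size: Optional[int] = None
) -> dict:
    """Read-count / length summary in the assembly-stats convention."""
    n = len(reads)
    total = sum(len(r) for r in reads)
    stats = {
        "n_reads": n,
        "total_bases": total,
        "mean_len": round(total / n, 2) if n else 0.0,
        "max_len": max((len(r) for r in reads), default=0),
    }
    if genome_size:
        stats["coverage"] = round(total / genome_size, 2)
    return stats


def plot_depth(profiles: dict[str, DepthProfile], path: str) -> None:
    """One panel of per-base depth per reference (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(profiles), 1, figsize=(8, 2 * len(profiles)))
    if len(profiles) == 1:
        axes = [axes]
    for ax, (name, prof) in zip(axes, sorted(profiles.items())):
        ax.fill_between(np.arange(prof.depth.size), prof.depth, step="mid")
        ax.set_ylabel("depth")
        ax.set_title(name, fontsize=9)
    axes[-1].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class PrimerPair:
    forward: str
    reverse: str
    max_mismatches: int = 0
    max_product: int = 20000

    def __post_init__(self) -> None:
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise InputError("primers must be at least 15 nt")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()


def _find_exact(seq: str, query: str) -> list[int]:
    out = []
    start = 0
    while True:
        i = seq.find(query, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def insilico_pcr(allele: SeqRecord, pair: PrimerPair) -> list[int]:
    """Predicted amplicon lengths for a primer pair on one allele.

    Exact, 3'-anchored matching (diagnostic PCR semantics): a product is
    reported for every forward-primer site paired with a downstream
    reverse-primer site within ``max_product`` bases, on either strand.
    """
    seq = allele.seq
    products = set()
    for fwd, rev in ((pair.forward, pair.reverse), (pair.reverse, pair.forward)):
        f_sites = _find_exact(seq, fwd)
        r_sites = _find_exact(seq, revcomp(rev))
        for f in f_sites:
            for r in r_sites:
                end = r + len(rev)
                length = end - f
                if 0 < length <= pair.max_product:
                    products.add((f, end))
    return sorted(end - start for start, end in products)
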