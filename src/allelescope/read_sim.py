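"""Seeded read simulation for a diploid-plus-derivative edited locus.

The generator emulates the sequencing design of the study: PacBio-style
long reads (log-normal lengths, mean 15 kb) at ~50X per allele and
Illumina-style 150 bp paired-end reads at high depth, drawn from a genotype
of three alleles - the 26 bp NHEJ insertion allele, the ~38 kb concatemer
allele, and its 18 kb deletion derivative at one tenth the abundance of the
others.  Every read carries a truth record (allele of origin, coordinates,
strand) so each downstream stage can be scored against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .allele_model import AlleleBlueprint, AlleleTruth, SegmentLibrary, build_allele
from .seq_core import InputError, SeqRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_GENOTYPE = {"alleleA": 1.0, "alleleB": 1.0, "alleleC": 0.1}


@dataclass
class Genotype:
    """Allele names with relative abundances (copy-number weights)."""

    abundances: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE)
    )

    def __post_init__(self) -> None:
        if not self.abundances:
            raise InputError("genotype must name at least one allele")
        if any(a <= 0 for a in self.abundances.values()):
            raise InputError("allele abundances must be positive")


@dataclass
class LongReadModel:
    """Log-normal read lengths with HiFi-like or CLR-like error rates."""

    mean_len: float = 15000.0
    sigma: float = 0.6
    min_len: int = 500
    max_len: int = 60000
    sub_rate: float = 0.01
    ins_rate: float = 0.005
    del_rate: float = 0.005
    seed: int = 0
    qual: int = 20

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.2:
                raise InputError(f"error rate {r} outside [0, 0.2]")
        if self.mean_len <= 0 or self.min_len <= 0:
            raise InputError("lengths must be positive")

    @classmethod
    def clr_like(cls, **kw) -> "LongReadModel":
        kw.setdefault("sub_rate", 0.05)
        kw.setdefault("ins_rate", 0.05)
        kw.setdefault("del_rate", 0.03)
        return cls(**kw)

    @property
    def mu(self) -> float:
        # mean of lognormal = exp(mu + sigma^2/2)
        return float(np.log(self.mean_len) - self.sigma**2 / 2)


@dataclass
class ShortReadModel:
    read_len: int = 150
    paired: bool = True
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    sub_rate: float = 0.001
    seed: int = 0
    qual: int = 30

    def __post_init__(self) -> None:
        if not 0 <= self.sub_rate <= 0.2:
            raise InputError("error rate outside [0, 0.2]")
        if self.insert_mean < 2 * self.read_len:
            warnings.warn(
                "insert_mean < 2*read_len: mates will overlap", stacklevel=2
            )


@dataclass
class ReadSet:
    reads: list[SeqRecord]
    truth: pd.DataFrame  # read_id, allele, start, end, strand

    def __len__(self) -> int:
        return len(self.reads)


def _mutate(
    seq: str,
    rng: np.random.Generator,
    sub: float,
    ins: float = 0.0,
    dele: float = 0.0,
) -> str:
    """Apply per-base substitution / insertion / deletion errors."""
    if not seq or (sub == 0 and ins == 0 and dele == 0):
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    u = rng.random(n)
    sub_idx = np.flatnonzero(u < sub)
    if sub_idx.size:
        # map A,C,G,T -> 0..3, shift by 1..3, map back
        code = np.zeros(256, dtype=np.uint8)
        code[ord("C")] = 1
        code[ord("G")] = 2
        code[ord("T")] = 3
        cur = code[arr[sub_idx]]
        shift = rng.integers(1, 4, size=sub_idx.size)
        arr[sub_idx] = _BASES[(cur + shift) % 4]
    if ins or dele:
        v = rng.random(n)
        rep = np.ones(n, dtype=np.int64)
        rep[v < dele] = 0
        ins_mask = (v >= dele) & (v < dele + ins)
        rep[ins_mask] = 2
        out = np.repeat(arr, rep)
        if ins_mask.any():
            # positions of the duplicated base inside the output
            starts = np.cumsum(rep) - rep
            dup_pos = starts[ins_mask] + 1
            out[dup_pos] = _BASES[rng.integers(0, 4, size=dup_pos.size)]
        arr = out
    return arr.tobytes().decode()


def _build_alleles(
    lib: SegmentLibrary,
    blueprints: dict[str, AlleleBlueprint],
    genotype: Genotype,
) -> dict[str, AlleleTruth]:
    out = {}
    for name in genotype.abundances:
        if name not in blueprints:
            raise InputError(f"genotype names unknown allele {name!r}")
        out[name] = build_allele(lib, blueprints[name])
    return out


def simulate_long(
    lib: SegmentLibrary,
    genotype: Genotype,
    model: LongReadModel,
    coverage_per_allele: float = 50.0,
    blueprints: Optional[dict[str, AlleleBlueprint]] = None,
) -> ReadSet:
    """Simulate long reads to ``coverage_per_allele`` x abundance per allele.

    Each allele receives reads until its base target (coverage x abundance x
    allele length) is met; read lengths are log-normal, capped at the allele
    length (short alleles therefore yield full-length reads, mirroring a
    2 kb locus read out of longer genomic molecules).  Circular alleles are
    sampled from their doubled sequence.
    """
    if coverage_per_allele <= 0:
        raise InputError("coverage must be positive")
    if blueprints is None:
        from .allele_model import builtin_blueprints

        blueprints = builtin_blueprints(lib)
    alleles = _build_alleles(lib, blueprints, genotype)
    rng = np.random.default_rng(model.seed)
    reads: list[SeqRecord] = []
    rows = []
    for name, ab in genotype.abundances.items():
        truth = alleles[name]
        source = truth.record.seq
        circular = blueprints[name].circular
        glen = len(source)
        template = source + source if circular else source
        target = coverage_per_allele * ab * glen
        emitted = 0
        i = 0
        while emitted < target:
            raw = rng.lognormal(mean=model.mu, sigma=model.sigma)
            length = int(min(max(raw, model.min_len), model.max_len, glen))
            max_start = (glen - 1) if circular else (glen - length)
            start = int(rng.integers(0, max_start + 1))
            frag = template[start : start + length]
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _mutate(
                frag if strand == "+" else revcomp(frag),
                rng,
                model.sub_rate,
                model.ins_rate,
                model.del_rate,
            )
            rid = f"{name}_long_{i}"
            reads.append(SeqRecord(rid, seq, [model.qual] * len(seq)))
            rows.append((rid, name, start, start + length, strand))
            emitted += length
            i += 1
    truth_df = pd.DataFrame(
        rows, columns=["read_id", "allele", "start", "end", "strand"]
    )
    return ReadSet(reads, truth_df)


def simulate_short(
    lib: SegmentLibrary,
    genotype: Genotype,
    model: ShortReadModel,
    coverage: float = 100.0,
    blueprints: Optional[dict[str, AlleleBlueprint]] = None,
) -> tuple[ReadSet, ReadSet]:
    """Simulate FR paired-end reads; returns (mate1, mate2) read sets."""
    if coverage <= 0:
        raise InputError("coverage must be positive")
    if blueprints is None:
        from .allele_model import builtin_blueprints

        blueprints = builtin_blueprints(lib)
    alleles = _build_alleles(lib, blueprints, genotype)
    rng = np.random.default_rng(model.seed)
    r1: list[SeqRecord] = []
    r2: list[SeqRecord] = []
    rows1, rows2 = [], []
    L = model.read_len
    for name, ab in genotype.abundances.items():
        truth = alleles[name]
        source = truth.record.seq
        circular = blueprints[name].circular
        glen = len(source)
        template = source + source if circular else source
        target = coverage * ab * glen
        emitted = 0
        i = 0
        while emitted < target:
            insert = int(rng.normal(model.insert_mean, model.insert_sd))
            insert = max(L, min(insert, glen))
            max_start = (glen - 1) if circular else (glen - insert)
            start = int(rng.integers(0, max_start + 1))
            frag = template[start : start + insert]
            if rng.random() < 0.5:
                frag = revcomp(frag)
                strand = "-"
            else:
                strand = "+"
            fwd = frag[:L]
            rev = revcomp(frag[-L:])
            rid = f"{name}_pair_{i}"
            r1.append(
                SeqRecord(
                    rid + "/1",
                    _mutate(fwd, rng, model.sub_rate),
                    [model.qual] * len(fwd),
                )
            )
            r2.append(
                SeqRecord(
                    rid + "/2",
                    _mutate(rev, rng, model.sub_rate),
                    [model.qual] * len(rev),
                )
            )
            rows1.append((rid + "/1", name, start, start + insert, strand))
            rows2.append((rid + "/2", name, start, start + insert, strand))
            emitted += 2 * L
            i += 1
    cols = ["read_id", "allele", "start", "end", "strand"]
    return (
        ReadSet(r1, pd.DataFrame(rows1, columns=cols)),
        ReadSet(r2, pd.DataFrame(rows2, columns=cols)),
    )


def make_decoy_genome(
    lib: SegmentLibrary,
    n_chrom: int = 2,
    lengths: Optional[list[int]] = None,
    seed: int = 99,
) -> list[SeqRecord]:
    """Random decoy chromosomes sharing no 25-mer with any donor segment."""
    from .allele_model import _kmer_set  # same k-mer convention as the library

    if lengths is None:
        lengths = [50000] * n_chrom
    if any(n <= 0 for n in lengths):
        raise InputError("decoy lengths must be positive")
    donor = set()
    for label in ("TEMPLATE", "PUC", "NHEJ_INSERT"):
        donor |= _kmer_set(lib[label].seq, 25)
    rng = np.random.default_rng(seed)
    out = []
    for i, n in enumerate(lengths):
        while True:
            seq = _BASES[rng.integers(0, 4, size=n)].tobytes().decode()
            if not (_kmer_set(seq, 25) & donor):
                break
        out.append(SeqRecord(f"decoy_{i}", seq))
    return out
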