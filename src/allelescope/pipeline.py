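"""End-to-end orchestration: simulate -> recruit -> resolve -> report.

A run is fully reproducible from a :class:`RunConfig` (seed plus every
stage threshold).  ``run_simulate`` emits the synthetic read sets and truth
tables; ``run_resolve`` executes recruitment, block-word structure calling,
cut-site indel refinement, short-read junction discovery and consensus
confirmation, returning a JSON-serialisable summary; ``run_report`` writes
the summary and the per-stage tables to an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import consensus as cns
from . import junction_finder as jf
from .allele_model import builtin_blueprints, make_library
from .profiling import readset_stats
from .read_sim import (
    Genotype,
    LongReadModel,
    ReadSet,
    ShortReadModel,
    simulate_long,
    simulate_short,
)
from .recruit import build_baits, recruit_reads
from .seq_core import InputError, SeqRecord, write_fasta, write_fastq
from .structure_caller import (
    CompositeReference,
    block_string,
    call_cutsite_indel,
    call_structures,
    cluster_blockstrings,
    map_subreads,
    tile_read,
)

log = logging.getLogger("allelescope")


@dataclass
class RunConfig:
    seed: int = 1
    length_overrides: dict = field(default_factory=dict)
    genotype: dict = field(default_factory=lambda: {"alleleA": 1.0, "alleleB": 1.0, "alleleC": 0.1})
    long_coverage: float = 50.0
    short_coverage: float = 100.0
    long_mean_len: float = 15000.0
    long_sigma: float = 0.6
    long_sub_rate: float = 0.01
    long_ins_rate: float = 0.005
    long_del_rate: float = 0.005
    short_sub_rate: float = 0.001
    min_hit_len: int = 500
    min_identity: float = 0.8
    window: int = 1000
    step: int = 500
    min_block_len: int = 300
    min_reads: int = 2
    min_clusters: int = 2
    abundance_cutoff: int = 3
    min_overlap: int = 16
    with_short_reads: bool = True
    with_consensus: bool = True
    max_msa_reads: int = 12
    outdir: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class Dataset:
    lib: object
    blueprints: dict
    long_reads: ReadSet
    short_reads: Optional[tuple[ReadSet, ReadSet]]


def run_simulate(config: RunConfig) -> Dataset:
    """Build the segment library and simulate the configured read sets."""
    if config.long_coverage <= 0:
        raise InputError("long_coverage must be positive")
    lib = make_library(config.seed, config.length_overrides or None)
    blueprints = builtin_blueprints(lib)
    genotype = Genotype(dict(config.genotype))
    long_model = LongReadModel(
        mean_len=config.long_mean_len,
        sigma=config.long_sigma,
        sub_rate=config.long_sub_rate,
        ins_rate=config.long_ins_rate,
        del_rate=config.long_del_rate,
        seed=config.seed + 1,
    )
    long_reads = simulate_long(
        lib, genotype, long_model, config.long_coverage, blueprints
    )
    short_reads = None
    if config.with_short_reads:
        short_model = ShortReadModel(sub_rate=config.short_sub_rate, seed=config.seed + 2)
        short_reads = simulate_short(
            lib, genotype, short_model, config.short_coverage, blueprints
        )
    log.info(
        "simulated %d long reads (%d bases)%s",
        len(long_reads),
        sum(len(r) for r in long_reads.reads),
        ""
        if short_reads is None
        else f" and {len(short_reads[0])} short-read pairs",
    )
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fastq(long_reads.reads, out / "long_reads.fastq")
        long_reads.truth.to_csv(out / "long_reads.truth.tsv", sep="\t", index=False)
        if short_reads:
            write_fastq(short_reads[0].reads, out / "short_reads_1.fastq")
            write_fastq(short_reads[1].reads, out / "short_reads_2.fastq")
            short_reads[0].truth.to_csv(
                out / "short_reads.truth.tsv", sep="\t", index=False
            )
        write_fasta(
            [SeqRecord(name, lib[name].seq) for name in ("TEMPLATE", "PUC")],
            out / "references.fasta",
        )
        (out / "config.json").write_text(config.to_json())
    return Dataset(lib, blueprints, long_reads, short_reads)


def run_resolve(config: RunConfig, dataset: Dataset) -> dict:
    """Execute the full inference chain on a dataset; returns the summary."""
    lib = dataset.lib
    blueprints = dataset.blueprints
    ref = CompositeReference.from_library(lib)
    summary: dict = {"stages": {}}

    # 1. recruitment against the bait set
    baits = build_baits(lib, blueprints)
    recruited, report = recruit_reads(
        dataset.long_reads, baits, config.min_hit_len, config.min_identity
    )
    log.info("recruited %d / %d long reads", len(recruited), len(dataset.long_reads))
    summary["stages"]["recruited_reads"] = len(recruited)
    summary["stages"]["input_reads"] = len(dataset.long_reads)
    if len(recruited) == 0:
        log.warning("no reads recruited; empty report")
        summary["structures"] = []
        return summary

    # 2. block words and clusters
    reads_by_id = {r.id: r for r in recruited.reads}
    blockstrings = {}
    words = {}
    for read in recruited.reads:
        subs = tile_read(read, config.window, config.step)
        hits = map_subreads(subs, ref)
        bs = block_string(read, hits, min_block_len=config.min_block_len)
        blockstrings[read.id] = bs
        words[read.id] = bs.symbols(ref)
    clusters = cluster_blockstrings(words)
    log.info("%d block-word clusters", len(clusters))
    summary["stages"]["n_clusters"] = len(clusters)

    # 3. structure calls + cut-site indels
    structures = call_structures(
        clusters, ref, min_reads=config.min_reads, min_clusters=config.min_clusters
    )
    for st in structures:
        if st.n_template_copies == 0:
            indel, ins_seq = call_cutsite_indel(st, ref, reads_by_id)
            st.cutsite_indel = indel
            st.cutsite_insert_seq = ins_seq
    log.info("%d structures called", len(structures))

    # 4. short-read junction discovery
    junctions = []
    if dataset.short_reads is not None:
        r1, r2 = dataset.short_reads
        edge_index = jf.build_edge_index(
            {"template": lib["TEMPLATE"].seq, "puc": lib["PUC"].seq}
        )
        selected, edge_counts = jf.select_reads(r1.reads + r2.reads, edge_index)
        trimmed = jf.error_trim(selected, config.abundance_cutoff)
        contigs = jf.assemble_greedy(trimmed, config.min_overlap)
        calls = jf.annotate_contigs(contigs, ref.refs, lib, cut=ref.cut)
        seen = set()
        for call in calls:
            sig = call.signature()
            if sig in seen:
                continue
            seen.add(sig)
            junctions.append(call)
        log.info(
            "%d short reads selected, %d contigs, %d distinct junctions",
            len(selected),
            len(contigs),
            len(junctions),
        )
        summary["stages"]["selected_short_reads"] = len(selected)
        summary["stages"]["n_contigs"] = len(contigs)

    # 5. consensus confirmation per junction substructure
    consensus_records = []
    if config.with_consensus:
        groups = cns.group_and_trim(
            blockstrings, words, structures, reads_by_id, ref
        )
        for group in groups:
            if group.n_reads < 2:
                continue
            rows = cns.msa(
                [s for _, s in group.segments], max_seqs=config.max_msa_reads
            )
            rec = cns.consensus_call(rows)
            consensus_records.append(
                {
                    "substructure": group.substructure_id,
                    "n_reads": group.n_reads,
                    "consensus_len": len(rec),
                }
            )

    summary["read_stats"] = readset_stats(dataset.long_reads.reads)
    summary["structures"] = [
        {
            "name": st.name,
            "word": [f"{n}{s}" for n, s in st.word],
            "n_template_copies": st.n_template_copies,
            "n_backbone_copies": st.n_backbone_copies,
            "insertion_length_bp": st.insertion_length_bp,
            "insertion_length_kb": st.insertion_length_kb,
            "n_support": st.n_support,
            "n_clusters": len(st.cluster_ids),
            "ambiguous": st.ambiguous,
            "cutsite_indel": st.cutsite_indel,
            "cutsite_insert_seq": st.cutsite_insert_seq,
        }
        for st in structures
    ]
    summary["junctions"] = [
        {
            "left": list(c.left),
            "right": list(c.right),
            "insert_len": c.insert_len,
            "insert_seq": c.insert_seq,
            "annotation": c.annotation,
        }
        for c in junctions
    ]
    summary["consensus"] = consensus_records
    return summary


def run_report(summary: dict, outdir: str | Path) -> list[Path]:
    """Write the summary bundle to ``outdir``; idempotent."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(p)
    if summary.get("structures"):
        import pandas as pd

        df = pd.DataFrame(summary["structures"])
        p = out / "structures.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    if summary.get("junctions"):
        import pandas as pd

        df = pd.DataFrame(
            [
                {
                    "left": "/".join(map(str, j["left"])),
                    "right": "/".join(map(str, j["right"])),
                    "insert_len": j["insert_len"],
                    "annotation": j["annotation"],
                }
                for j in summary["junctions"]
            ]
        )
        p = out / "junctions.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    manifest = out / "manifest.json"
    manifest.write_text(
        json.dumps({"files": sorted(str(w.name) for w in written)}, indent=2) + "\n"
    )
    written.append(manifest)
    return written


def run_all(config: RunConfig) -> dict:
    dataset = run_simulate(config)
    summary = run_resolve(config, dataset)
    if config.outdir:
        run_report(summary, config.outdir)
    return summary
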