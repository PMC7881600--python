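import random

import numpy as np
import pytest

from allelescope.allele_model import GRNA_SITE_SEQ
from allelescope.junction_finder import (
    annotate_contigs,
    assemble_greedy,
    build_edge_index,
    error_trim,
    select_reads,
)
from allelescope.seq_core import InputError, SeqRecord, kmers, revcomp


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def edge_index(lib):
    return build_edge_index(
        {"template": lib["TEMPLATE"].seq, "puc": lib["PUC"].seq}
    )


# ---------------------------------------------------------------------------
# edge k-mer index
# ---------------------------------------------------------------------------


def test_each_50bp_edge_gives_26_kmers(edge_index):
    assert len(edge_index.edges) == 4  # 2 references x 2 edges
    for kms in edge_index.edges.values():
        assert len(kms) == 26


def test_edge_len_equal_k_gives_one_kmer(lib):
    idx = build_edge_index({"puc": lib["PUC"].seq}, edge_len=25, k=25)
    assert all(len(v) == 1 for v in idx.edges.values())


def test_edge_len_below_k_rejected(lib):
    with pytest.raises(InputError):
        build_edge_index({"puc": lib["PUC"].seq}, edge_len=20, k=25)


# ---------------------------------------------------------------------------
# read selection
# ---------------------------------------------------------------------------


def test_select_edge_and_revcomp_reads(lib, edge_index):
    edge = lib["TEMPLATE"].seq[:50]
    rng = np.random.default_rng(0)
    pad = _rand(rng, 50)
    selected, counts = select_reads(
        [
            SeqRecord("fwd", edge + pad),
            SeqRecord("rev", revcomp(pad + edge)),
            SeqRecord("none", _rand(rng, 150)),
        ],
        edge_index,
    )
    assert {r.id for r in selected} == {"fwd", "rev"}
    assert counts.set_index("edge").loc["template:start", "n_selected_reads"] == 2


def test_select_matches_containment_oracle(lib, edge_index):
    """select_reads equals the brute-force substring containment oracle."""
    rng = np.random.default_rng(1)
    tmpl = lib["TEMPLATE"].seq
    reads = []
    for i in range(300):
        if i % 3 == 0:
            pos = int(rng.integers(0, len(tmpl) - 150))
            reads.append(SeqRecord(f"t{i}", tmpl[pos : pos + 150]))
        else:
            reads.append(SeqRecord(f"x{i}", _rand(rng, 150)))
    selected, _ = select_reads(reads, edge_index)
    all_kmers = set()
    for kms in edge_index.edges.values():
        all_kmers.update(kms)
        all_kmers.update(revcomp(k) for k in kms)
    oracle = {
        r.id
        for r in reads
        if any(km in all_kmers for km in kmers(r.seq, 25))
    }
    assert {r.id for r in selected} == oracle


# ---------------------------------------------------------------------------
# abundance trimming
# ---------------------------------------------------------------------------


def _deep_tiling(rng, region, copies=3):
    reads = []
    for c in range(copies):
        for i in range(0, 250, 5):
            reads.append(SeqRecord(f"c{c}_r{i}", region[i : i + 150]))
    return reads


def test_error_trim_keeps_clean_deep_reads():
    rng = np.random.default_rng(2)
    reads = _deep_tiling(rng, _rand(rng, 400))
    trimmed = error_trim(reads, abundance_cutoff=3)
    assert [(r.id, r.seq) for r in trimmed] == [(r.id, r.seq) for r in reads]


def test_error_trim_cuts_at_isolated_error():
    rng = np.random.default_rng(3)
    region = _rand(rng, 400)
    reads = _deep_tiling(rng, region)
    bad = list(region[50:200])
    bad[75] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[75]]
    reads.append(SeqRecord("err", "".join(bad)))
    trimmed = error_trim(reads, abundance_cutoff=3)
    by_id = {r.id: r for r in trimmed}
    assert len(by_id["err"]) == 75  # truncated at the error
    # all clean reads untouched
    assert all(len(by_id[r.id]) == 150 for r in reads if r.id != "err")


def test_error_trim_cutoff_one_is_identity():
    rng = np.random.default_rng(4)
    reads = [SeqRecord(f"r{i}", _rand(rng, 100)) for i in range(5)]
    trimmed = error_trim(reads, abundance_cutoff=1)
    assert [(r.id, r.seq) for r in trimmed] == [(r.id, r.seq) for r in reads]


# ---------------------------------------------------------------------------
# greedy assembly
# ---------------------------------------------------------------------------


def test_assembly_reconstructs_tiled_region():
    rng = np.random.default_rng(5)
    region = _rand(rng, 600)
    reads = [SeqRecord(f"r{i}", region[i : i + 150]) for i in range(0, 451, 50)]
    contigs = assemble_greedy(reads)
    assert len(contigs) == 1
    assert region in contigs[0].seq or revcomp(region) in contigs[0].seq


def test_assembly_respects_min_overlap():
    rng = np.random.default_rng(6)
    a_seq = _rand(rng, 100)
    b_seq = a_seq[-10:] + _rand(rng, 90)  # overlap 10 < 16
    contigs = assemble_greedy([SeqRecord("a", a_seq), SeqRecord("b", b_seq)])
    assert len(contigs) == 2


def test_assembly_empty_input():
    assert assemble_greedy([]) == []


def test_assembly_invariant_to_read_order():
    rng = np.random.default_rng(7)
    region = _rand(rng, 500)
    reads = [SeqRecord(f"r{i}", region[i : i + 120]) for i in range(0, 381, 20)]
    base = sorted(c.seq for c in assemble_greedy(reads))
    for seed in (1, 2, 3):
        shuffled = list(reads)
        random.Random(seed).shuffle(shuffled)
        assert sorted(c.seq for c in assemble_greedy(shuffled)) == base


def test_min_overlap_floor():
    with pytest.raises(InputError):
        assemble_greedy([], min_overlap=10)


# ---------------------------------------------------------------------------
# contig annotation
# ---------------------------------------------------------------------------


def test_annotate_footprint_fragment_and_hr(lib, ref):
    tmpl = lib["TEMPLATE"].seq
    puc = lib["PUC"].seq
    chr_l = lib["CHR17_L"].seq
    contigs = [
        # internal same-orientation junction with a 20 bp gRNA footprint
        SeqRecord("c_foot", tmpl[-150:] + GRNA_SITE_SEQ[:20] + tmpl[:150]),
        # junction carrying a 56 bp backbone fragment across an inversion
        SeqRecord("c_frag", revcomp(tmpl)[-150:] + puc[:56] + tmpl[:150]),
        # footprint-free boundary between genomic flank and truncated copy
        SeqRecord("c_hr", chr_l[-150:] + tmpl[22:172]),
        # contig wholly inside the template: no junction
        SeqRecord("c_none", tmpl[1000:1400]),
    ]
    calls = annotate_contigs(contigs, ref.refs, lib)
    by_contig = {}
    for c in calls:
        by_contig.setdefault(c.contig_id, []).append(c)
    assert "c_none" not in by_contig
    foot = by_contig["c_foot"][0]
    assert foot.insert_len == 20
    assert foot.annotation == "partial_gRNA_footprint(20)"
    frag = by_contig["c_frag"][0]
    assert frag.insert_len == 56
    assert frag.annotation == "backbone_fragment(56)"
    assert frag.insert_seq in (puc[:56], revcomp(puc[:56]))
    hr = by_contig["c_hr"][0]
    assert hr.insert_len == 0
    assert hr.annotation == "HR_boundary"
    assert {hr.left[0], hr.right[0]} == {"CHR17_L", "TEMPLATE"}
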