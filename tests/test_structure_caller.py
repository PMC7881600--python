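import pytest

import allelescope as a
from allelescope.allele_model import AlleleBlueprint, Block
from allelescope.read_sim import Genotype, LongReadModel, simulate_long
from allelescope.seq_core import InputError, SeqRecord
from allelescope.structure_caller import (
    block_string,
    call_cutsite_indel,
    call_structures,
    canonical,
    cluster_blockstrings,
    map_subreads,
    rc_symbols,
    tile_read,
)


def _word(read, ref):
    subs = tile_read(read)
    hits = map_subreads(subs, ref)
    return block_string(read, hits).symbols(ref)


def _full_read(alleles, name, rc=False):
    seq = alleles[name].record.seq
    rec = SeqRecord(f"{name}_full", seq)
    return rec.reverse_complement("_rc") if rc else rec


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "length,expected_starts",
    [
        (3000, [0, 500, 1000, 1500, 2000]),
        (800, [0]),
        (1000, [0]),
        (1001, [0, 500]),
    ],
)
def test_tile_read_starts(length, expected_starts):
    read = SeqRecord("r", "A" * length)
    subs = tile_read(read)
    assert [s for s, _ in subs] == expected_starts
    # trailing fragment is merged: last subread is at least window - step
    assert all(len(rec) >= 500 for _, rec in subs)
    # consecutive subreads overlap by exactly step
    for (s1, r1), (s2, _) in zip(subs, subs[1:]):
        assert s1 + len(r1) - s2 == 500 or s2 == subs[-1][0]


def test_tile_read_overlap_is_500():
    read = SeqRecord("r", "A" * 5000)
    subs = tile_read(read)
    for (s1, r1), (s2, r2) in zip(subs, subs[1:]):
        assert s1 + len(r1) - s2 >= 500


def test_tile_empty_and_bad_params():
    assert tile_read(SeqRecord("r", "A")) == [(0, tile_read(SeqRecord("r", "A"))[0][1])]
    with pytest.raises(InputError):
        tile_read(SeqRecord("r", "ACGT"), window=500, step=500)


# ---------------------------------------------------------------------------
# subread mapping and block words
# ---------------------------------------------------------------------------


def test_subread_in_template_maps_exactly(lib, ref):
    sub = SeqRecord("s", lib["TEMPLATE"].seq[2000:3000])
    hits = map_subreads([(0, sub)], ref)
    assert hits[0][1].target_id == "template"
    assert hits[0][1].identity == 1.0


def test_subread_from_decoy_maps_to_decoy(lib, blueprints):
    from allelescope.read_sim import make_decoy_genome
    from allelescope.structure_caller import CompositeReference

    decoys = make_decoy_genome(lib, 1, [6000], seed=2)
    ref2 = CompositeReference.from_library(lib, decoys=decoys)
    sub = SeqRecord("s", decoys[0].seq[1000:2000])
    hits = map_subreads([(0, sub)], ref2)
    assert hits[0][1].target_id == "decoy_0"


@pytest.mark.parametrize(
    "name,expected",
    [
        ("wildtype", (("LOCUS", "+"),)),
        ("alleleA", (("LOCUS", "+"),)),
        (
            "alleleC",
            (
                ("L", "+"),
                ("T", "+"),
                ("P", "+"),
                ("T", "+"),
                ("T", "-"),
                ("R", "+"),
            ),
        ),
        (
            "alleleB",
            (
                ("L", "+"),
                ("T", "+"),
                ("P", "+"),
                ("T", "-"),
                ("T", "-"),
                ("T", "+"),
                ("T", "+"),
                ("T", "+"),
                ("T", "-"),
                ("R", "+"),
            ),
        ),
    ],
)
def test_full_length_block_words(alleles, ref, name, expected):
    """Error-free full-span reads reproduce every blueprint's block word."""
    assert _word(_full_read(alleles, name), ref) == expected


def test_inverted_repeat_junction_word(alleles, ref):
    """A read across an inversion junction reads T+ then T-."""
    b = alleles["alleleB"].record
    # junction between the T+ copy ending and T- copy starting (outer pair)
    truth = [x for x in alleles["alleleB"].blocks if x.label == "TEMPLATE"]
    plus_then_minus = next(
        (l, r)
        for l, r in zip(truth, truth[1:])
        if l.orientation == "+" and r.orientation == "-" and r.start - l.end < 100
    )
    lo = plus_then_minus[0].start + 2000
    hi = plus_then_minus[1].end - 2000
    read = SeqRecord("inv", b.seq[lo:hi])
    assert _word(read, ref) == (("T", "+"), ("T", "-"))


def test_read_within_single_copy_gives_one_block(lib, ref):
    read = SeqRecord("r", lib["TEMPLATE"].seq[200:4800])
    word = _word(read, ref)
    assert word == (("T", "+"),)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def test_cluster_canonicalisation(alleles, ref):
    fwd = _full_read(alleles, "alleleC")
    rev = _full_read(alleles, "alleleC", rc=True)
    words = {r.id: _word(r, ref) for r in (fwd, rev)}
    clusters = cluster_blockstrings(words)
    assert len(clusters) == 1
    assert clusters[0].size == 2


def test_rc_symbols_involution():
    w = (("L", "+"), ("T", "-"), ("P", "+"))
    assert rc_symbols(rc_symbols(w)) == w
    assert canonical(w) == canonical(rc_symbols(w))


# ---------------------------------------------------------------------------
# structure calling
# ---------------------------------------------------------------------------


def _resolve(reads, ref, **kw):
    words = {r.id: _word(r, ref) for r in reads}
    clusters = cluster_blockstrings(words)
    return call_structures(clusters, ref, **kw), words


def test_full_span_reads_recover_every_blueprint(alleles, ref):
    """Oracle equivalence on reads covering whole alleles."""
    reads = []
    for name in ("alleleA", "alleleB", "alleleC"):
        reads.append(_full_read(alleles, name))
        reads.append(_full_read(alleles, name, rc=True))
    calls, words = _resolve(reads, ref)
    by_copies = {c.n_template_copies: c for c in calls}
    assert set(by_copies) == {0, 3, 7}
    assert by_copies[7].word == canonical(words["alleleB_full"]) or by_copies[
        7
    ].word == rc_symbols(canonical(words["alleleB_full"]))
    assert by_copies[7].n_backbone_copies == 1
    assert by_copies[3].n_backbone_copies == 1


def test_wildtype_only_simulation(alleles, ref):
    reads = [_full_read(alleles, "wildtype"), _full_read(alleles, "wildtype", rc=True)]
    calls, _ = _resolve(reads, ref)
    assert len(calls) == 1
    assert calls[0].n_template_copies == 0
    assert calls[0].insertion_length_bp == 0


def test_single_read_not_reported(alleles, ref):
    calls, _ = _resolve([_full_read(alleles, "alleleC")], ref)
    assert calls == []


def test_support_rule_thresholds_validated(ref):
    with pytest.raises(InputError):
        call_structures([], ref, min_reads=0)


def test_support_monotone_in_coverage(lib, blueprints, ref):
    """Raising coverage never loses a true structure."""
    found = {}
    for cov in (20, 60):
        gt = Genotype({"alleleB": 1.0})
        rs = simulate_long(
            lib, gt, LongReadModel(seed=21), coverage_per_allele=cov, blueprints=blueprints
        )
        calls, _ = _resolve(rs.reads, ref)
        found[cov] = {c.word for c in calls if not c.ambiguous}
    assert found[20] <= found[60]
    assert any(c == 7 for c in {len([s for s in w if s[0] == "T"]) for w in found[60]})


# ---------------------------------------------------------------------------
# cut-site indels
# ---------------------------------------------------------------------------


def test_cutsite_insertion_recovered(lib, alleles, ref):
    reads = [
        _full_read(alleles, "alleleA"),
        _full_read(alleles, "alleleA", rc=True),
    ]
    calls, _ = _resolve(reads, ref)
    st = next(c for c in calls if c.n_template_copies == 0)
    reads_by_id = {r.id: r for r in reads}
    indel, seq = call_cutsite_indel(st, ref, reads_by_id)
    assert indel == 26
    assert seq == lib["NHEJ_INSERT"].seq


def test_cutsite_wildtype_is_zero(alleles, ref):
    reads = [_full_read(alleles, "wildtype"), _full_read(alleles, "wildtype", rc=True)]
    calls, _ = _resolve(reads, ref)
    indel, seq = call_cutsite_indel(calls[0], ref, {r.id: r for r in reads})
    assert indel == 0 and seq == ""


def test_cutsite_deletion_recovered(lib, ref):
    """A synthetic 9 bp deletion allele is called as -9."""
    bp = AlleleBlueprint(
        "del9",
        [Block("CHR17_L", "+", (0, 995)), Block("CHR17_R", "+", (4, 1000))],
    )
    truth = a.build_allele(lib, bp)
    reads = [
        SeqRecord("d1", truth.record.seq),
        SeqRecord("d2", truth.record.seq).reverse_complement("_rc"),
    ]
    calls, _ = _resolve(reads, ref)
    assert len(calls) == 1
    indel, _ = call_cutsite_indel(calls[0], ref, {r.id: r for r in reads})
    assert indel == -9


def test_cutsite_requires_template_free_structure(alleles, ref):
    reads = [
        _full_read(alleles, "alleleC"),
        _full_read(alleles, "alleleC", rc=True),
    ]
    calls, _ = _resolve(reads, ref)
    with pytest.raises(InputError):
        call_cutsite_indel(calls[0], ref, {})
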