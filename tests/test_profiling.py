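import numpy as np
import pytest

from allelescope.profiling import (
    DepthProfile,
    PrimerPair,
    depth_profile,
    insilico_pcr,
    off_target_scan,
    readset_stats,
)
from allelescope.read_sim import (
    Genotype,
    ShortReadModel,
    make_decoy_genome,
    simulate_short,
)
from allelescope.seq_core import InputError, SeqRecord, revcomp


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_single_read_depth_is_one_over_its_span():
    rng = np.random.default_rng(0)
    ref = _rand(rng, 1000)
    reads = [SeqRecord("r", ref[200:350])]
    profiles = depth_profile(reads, {"ref": ref})
    d = profiles["ref"].depth
    assert d[200:350].tolist() == [1] * 150
    assert d.sum() == 150


def test_depth_conservation(lib, blueprints):
    """Summed depth equals summed aligned span lengths across the panel."""
    gt = Genotype({"alleleA": 1.0})
    r1, r2 = simulate_short(
        lib, gt, ShortReadModel(sub_rate=0, seed=1), coverage=5, blueprints=blueprints
    )
    panel = {"locus": lib["CHR17_L"].seq + lib["CHR17_R"].seq, "puc": lib["PUC"].seq}
    reads = r1.reads + r2.reads
    profiles = depth_profile(reads, panel)
    total_depth = sum(p.depth.sum() for p in profiles.values())
    assert total_depth > 0
    # recompute aligned bases independently
    from allelescope.seq_core import SeedIndex, align_local

    index = SeedIndex(panel, k=15)
    aligned = 0
    for read in reads:
        hits = align_local(read, index, min_score=40)
        if hits:
            aligned += hits[0].target_span[1] - hits[0].target_span[0]
    assert total_depth == aligned


def test_depth_no_reads_all_zero():
    profiles = depth_profile([], {"ref": "ACGT" * 100})
    assert profiles["ref"].depth.sum() == 0
    assert profiles["ref"].mean == 0.0


def test_multicopy_enrichment_direction(lib, blueprints, alleles):
    """Template-unique depth exceeds locus-unique depth at equal allelic coverage."""
    gt = Genotype({"alleleA": 1.0, "alleleB": 1.0})
    r1, r2 = simulate_short(
        lib, gt, ShortReadModel(sub_rate=0, seed=2), coverage=20, blueprints=blueprints
    )
    panel = {
        "template": lib["TEMPLATE"].seq,
        "nhej": alleles["alleleA"].record.seq,
        "puc": lib["PUC"].seq,
    }
    profiles = depth_profile(r1.reads + r2.reads, panel)
    # unique intervals: SRY+GFP inside the template, the flanks in the locus
    sry_gfp = profiles["template"].depth[1022 : 1022 + 3100]
    locus_unique = profiles["nhej"].depth[200:800]
    assert sry_gfp.mean() > locus_unique.mean()


def test_off_target_clean_simulation_is_empty(lib, blueprints):
    decoys = make_decoy_genome(lib, 1, [10000], seed=5)
    panel = {d.id: d.seq for d in decoys}
    panel["locus"] = lib["CHR17_L"].seq + lib["CHR17_R"].seq
    rng = np.random.default_rng(6)
    reads = [
        SeqRecord(f"d{i}", decoys[0].seq[i * 500 : i * 500 + 500]) for i in range(10)
    ]
    flagged = off_target_scan(reads, panel, lib)
    assert flagged.empty


def test_off_target_planted_insertion_detected(lib):
    decoys = make_decoy_genome(lib, 1, [10000], seed=7)
    panel = {d.id: d.seq for d in decoys}
    panel["locus"] = lib["CHR17_L"].seq + lib["CHR17_R"].seq
    d = decoys[0].seq
    planted = d[:400] + lib["TEMPLATE"].seq[2000:2100] + d[400:800]
    reads = [SeqRecord("planted", planted), SeqRecord("clean", d[2000:2800])]
    flagged = off_target_scan(reads, panel, lib)
    assert list(flagged.read_id) == ["planted"]


def test_off_target_empty_readset(lib):
    decoys = make_decoy_genome(lib, 1, [5000], seed=8)
    flagged = off_target_scan([], {d.id: d.seq for d in decoys}, lib)
    assert flagged.empty


@pytest.mark.parametrize(
    "lengths,mean,max_len",
    [([100], 100.0, 100), ([100, 200], 150.0, 200)],
)
def test_readset_stats_small(lengths, mean, max_len):
    reads = [SeqRecord(f"r{i}", "A" * n) for i, n in enumerate(lengths)]
    stats = readset_stats(reads)
    assert stats["mean_len"] == mean
    assert stats["max_len"] == max_len
    assert stats["total_bases"] == sum(lengths)


def test_readset_stats_mean_times_n_is_total():
    rng = np.random.default_rng(9)
    reads = [SeqRecord(f"r{i}", "A" * int(rng.integers(50, 500))) for i in range(37)]
    stats = readset_stats(reads)
    assert abs(stats["mean_len"] * stats["n_reads"] - stats["total_bases"]) < 0.5 * 37


def test_insilico_pcr_product_arithmetic(lib, alleles):
    """A cut-site insertion of d bases shifts the product by exactly d."""
    wt = alleles["wildtype"].record
    fwd = wt.seq[700:720]
    rev = revcomp(wt.seq[1280:1300])
    pair = PrimerPair(fwd, rev)
    assert insilico_pcr(wt, pair) == [600]
    nhej = alleles["alleleA"].record
    assert insilico_pcr(nhej, pair) == [626]
    b = alleles["alleleB"].record  # 38.8 kb insertion exceeds max product
    assert insilico_pcr(b, pair) == []


def test_insilico_pcr_absent_primers(alleles):
    pair = PrimerPair("ACGTACGTACGTACGTACGT", "TTTTACGTACGTACGTACGT")
    assert insilico_pcr(alleles["wildtype"].record, pair) == []


def test_primer_length_contract():
    with pytest.raises(InputError):
        PrimerPair("ACGT", "ACGTACGTACGTACGT")
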