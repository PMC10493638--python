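import numpy as np
import pytest

from triadkit import features as ft
from triadkit.io import GeneModel, GenomeSequences

RNG = np.random.default_rng(123)


def random_dna(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def chrom_with_telomeres(n5, n3, middle=5000, rng=RNG):
    return (ft.TELOMERE_UNIT_5P * n5 + random_dna(middle, rng)
            + ft.TELOMERE_UNIT_3P * n3)


# ---------------------------------------------------------------------------
# Telomeres
# ---------------------------------------------------------------------------

def test_perfect_tract_called_exactly():
    seq = chrom_with_telomeres(0, 100)
    genome = GenomeSequences(records=[("c1", seq)])
    calls = ft.find_telomeres(genome)
    assert len(calls) == 1
    c = calls[0]
    assert (c.end, c.length_bp, c.purity) == ("3prime", 700, 1.0)
    assert c.stop == len(seq)
    assert c.copy_estimate == 100


def test_no_repeat_within_offset_no_call():
    genome = GenomeSequences(records=[("c1", random_dna(30_000))])
    assert ft.find_telomeres(genome) == []


def test_planted_lengths_recovered_exactly():
    """Planted perfect tracts of 50 random lengths come back with no
    over- or under-trimming at either end."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        n5 = int(rng.integers(100, 1000))
        n3 = int(rng.integers(100, 1000))
        seq = chrom_with_telomeres(n5, n3, middle=3000, rng=rng)
        genome = GenomeSequences(records=[("c1", seq)])
        calls = {c.end: c for c in ft.find_telomeres(genome)}
        assert calls["5prime"].length_bp == 7 * n5
        assert calls["3prime"].length_bp == 7 * n3
        assert calls["5prime"].start == 1
        assert calls["3prime"].stop == len(seq)


def test_mismatched_units_tolerated_within_purity():
    # 50 good, 2 bad, 150 good units: purity 200/202 > 0.9
    bad = "AAAAAAA"
    seq = (ft.TELOMERE_UNIT_5P * 50 + bad * 2 + ft.TELOMERE_UNIT_5P * 150
           + random_dna(2000))
    genome = GenomeSequences(records=[("c1", seq)])
    c = [x for x in ft.find_telomeres(genome) if x.end == "5prime"][0]
    assert c.length_bp == 7 * 202
    assert c.purity == pytest.approx(200 / 202)


def test_t2t_classification():
    both = chrom_with_telomeres(120, 120)
    one = chrom_with_telomeres(0, 120)
    none = random_dna(5000)
    genome = GenomeSequences(records=[("a", both), ("b", one), ("c", none)])
    calls = ft.find_telomeres(genome)
    status, n = ft.classify_t2t(calls, genome)
    assert status == {"a": "T2T", "b": "one-ended", "c": "none"}
    assert n == 1


def test_t2t_recovers_planted_counts(small_sim):
    _cfg, genomes, *_rest, truth, _counts = small_sim
    for hap, genome in genomes.items():
        calls = ft.find_telomeres(genome)
        _status, n = ft.classify_t2t(calls, genome)
        planted = sum(1 for chrom, ends in truth.telomeres.items()
                      if chrom.startswith(hap) and len(ends) == 2)
        assert n == planted
        for c in calls:
            assert c.length_bp == 7 * truth.telomeres[c.chrom][c.end]


# ---------------------------------------------------------------------------
# Tandem arrays
# ---------------------------------------------------------------------------

def test_planted_array_found_with_exact_copies():
    unit = random_dna(135)
    seq = random_dna(20_000) + unit * 1000 + random_dna(20_000)
    calls = ft.find_tandem_arrays("c1", seq, unit_length_range=(100, 200),
                                  min_array_bp=10_000)
    assert len(calls) == 1
    c = calls[0]
    assert c.unit_length == 135
    assert c.copy_number == pytest.approx(1000, rel=0.01)


def test_random_sequence_has_no_large_array():
    rng = np.random.default_rng(17)
    for _ in range(10):
        seq = random_dna(60_000, rng)
        calls = ft.find_tandem_arrays("c1", seq, (100, 200),
                                      min_array_bp=10_000)
        assert calls == []


def test_longest_array_is_centromere_candidate():
    u1, u2 = random_dna(120), random_dna(150)
    seq = (random_dna(5_000) + u2 * 134  # ~20 kb
           + random_dna(30_000) + u1 * 417  # ~50 kb
           + random_dna(5_000))
    genome = GenomeSequences(records=[("c1", seq)])
    cand = ft.centromere_candidates(genome, (100, 200), 10_000)["c1"]
    assert cand is not None
    assert cand.unit_length == 120


def test_centromere_matches_truth(small_sim):
    _cfg, genomes, *_ = small_sim
    truth = small_sim[4]
    cands = ft.centromere_candidates(genomes["H2"])
    for chrom, c in cands.items():
        t_start, t_stop, t_unit = truth.centromeres[chrom]
        assert c is not None
        assert c.unit_length == t_unit
        assert abs(c.start - t_start) <= t_unit
        assert abs(c.stop - t_stop) <= t_unit


# ---------------------------------------------------------------------------
# NLR status and clusters
# ---------------------------------------------------------------------------

def gene(gid, chrom, start, end):
    return GeneModel(gene_id=gid, chrom=chrom, strand="+", start=start,
                     end=end)


GENES = [gene("g1", "chr1", 1000, 2000), gene("g2", "chr1", 5000, 6000)]


def test_locus_inside_gene_is_genic():
    st = ft.nlr_status([("chr1", 1200, 1400, "L1")], GENES)
    assert st[0].status == "genic"
    assert st[0].overlapping_gene == "g1"


def test_locus_between_genes_is_intergenic():
    st = ft.nlr_status([("chr1", 3000, 3200, "L1")], GENES)
    assert st[0].status == "intergenic"
    assert st[0].overlapping_gene is None


def test_locus_overlapping_two_genes_takes_larger_overlap():
    genes = [gene("gA", "chr1", 100, 200), gene("gB", "chr1", 190, 400)]
    st = ft.nlr_status([("chr1", 150, 300, "L1")], genes)
    assert st[0].overlapping_gene == "gB"  # 111 bp vs 51 bp overlap


def test_unknown_chromosome_is_error():
    with pytest.raises(KeyError, match="chrX"):
        ft.nlr_status([("chrX", 1, 10, "L1")], GENES)


def test_status_partitions_loci(small_sim):
    _cfg, _genomes, models, _hits, truth, _counts = small_sim
    loci = [(r["chrom"], r["start"], r["stop"], r["locus_id"])
            for r in truth.nlr]
    allm = [m for ms in models.values() for m in ms]
    st = ft.nlr_status(loci, allm)
    assert len(st) == len(loci)
    by_id = {l.locus_id: l.status for l in st}
    for r in truth.nlr:
        assert by_id[r["locus_id"]] == r["status"]


def loci_row(chrom, start, width=500, status="intergenic", i=[0]):
    i[0] += 1
    return ft.NLRLocusStatus(locus_id=f"L{i[0]}", chrom=chrom, start=start,
                             stop=start + width, status=status)


def test_cluster_ratio_string_all_pseudogenized():
    """26 loci within ~780 kb, none genic: reported as '0/26'."""
    loci = [loci_row("Chr03", 43_020_000 + k * 30_000) for k in range(26)]
    out = ft.cluster_nlr(loci, max_gap=200_000, min_loci=5)
    assert len(out) == 1
    assert out[0].ratio == "0/26"
    assert out[0].location_mb.startswith("43.02")


def test_far_apart_loci_split_into_clusters():
    loci = ([loci_row("chr1", 1_000 + k * 10_000) for k in range(5)]
            + [loci_row("chr1", 2_000_000 + k * 10_000) for k in range(5)])
    out = ft.cluster_nlr(loci, max_gap=200_000, min_loci=5)
    assert len(out) == 2
    spans = [(c.start, c.stop) for c in out]
    assert spans[0][1] < spans[1][0]


def test_small_groups_not_reported():
    loci = [loci_row("chr1", 1_000 + k * 10_000) for k in range(4)]
    assert ft.cluster_nlr(loci, max_gap=200_000, min_loci=5) == []


def test_cluster_invariant_to_input_order():
    loci = [loci_row("chr1", 1_000 + k * 50_000) for k in range(8)]
    fwd = ft.cluster_nlr(list(loci), max_gap=200_000, min_loci=5)
    rev = ft.cluster_nlr(list(reversed(loci)), max_gap=200_000, min_loci=5)
    assert [(c.chrom, c.start, c.stop, c.ratio) for c in fwd] == \
        [(c.chrom, c.start, c.stop, c.ratio) for c in rev]
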