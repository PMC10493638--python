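import itertools
import math

import numpy as np
import pandas as pd
import pytest

from triadkit import expression as ex
from triadkit import triads as tr
from triadkit.io import CountsTable, GeneModel


def make_counts(counts, lengths, samples):
    df = pd.DataFrame(counts, index=list(lengths), columns=samples)
    return CountsTable(counts=df,
                       lengths=pd.Series(lengths),
                       tissues={s: s.split("_")[0] for s in samples})


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def test_tpm_symmetry_and_hand_values():
    t = make_counts([[10], [10]], {"g1": 1000, "g2": 1000}, ["root"])
    tpm = ex.compute_tpm(t)
    assert tpm["root"].tolist() == [500_000.0, 500_000.0]

    t = make_counts([[10], [10]], {"g1": 1000, "g2": 2000}, ["root"])
    tpm = ex.compute_tpm(t)
    assert tpm["root"]["g1"] == pytest.approx(2e6 / 3)
    assert tpm["root"]["g2"] == pytest.approx(1e6 / 3)


def test_tpm_single_gene_and_zero_sample():
    t = make_counts([[7, 0]], {"g1": 500}, ["root", "leaf"])
    tpm = ex.compute_tpm(t)
    assert tpm["root"]["g1"] == pytest.approx(1e6)
    assert tpm["leaf"]["g1"] == 0.0


def test_tpm_columns_sum_to_a_million(small_sim):
    *_, counts = small_sim
    tpm = ex.compute_tpm(counts)
    for col in tpm.columns:
        assert tpm[col].sum() == pytest.approx(1e6, rel=1e-6)


def test_replicates_averaged_per_tissue():
    t = make_counts([[10, 30]], {"g1": 500}, ["root_r1", "root_r2"])
    tpm = ex.compute_tpm(t)
    by_tissue = ex.tpm_by_tissue(tpm, t.tissues)
    assert list(by_tissue.columns) == ["root"]
    assert by_tissue["root"]["g1"] == pytest.approx(1e6)


# ---------------------------------------------------------------------------
# Expression filter
# ---------------------------------------------------------------------------

def triad(tid, genes):
    return tr.Triad(triad_id=tid, genes=genes, mean_identity=95.0)


def part_of(triads):
    return tr.AllelePartition(triads=triads, pairs=[], singletons=[])


def test_filter_is_strictly_greater_than_half_tpm():
    t = triad("T1", {"H1": "a", "H2": "b", "H3": "c"})
    tpm = pd.DataFrame({"root": [0.5, 0.5, 0.5], "leaf": [0.5, 0.5, 0.5]},
                       index=["a", "b", "c"])
    kept, flags = ex.filter_expressed(part_of([t]), tpm)
    assert kept == []  # 0.5 exactly is NOT expressed
    tpm.loc["a", "root"] = 0.6
    kept, flags = ex.filter_expressed(part_of([t]), tpm)
    assert [k.triad_id for k in kept] == ["T1"]
    assert flags["n_expressed_homoeologs"].tolist() == [1]


def test_filter_empty_triad_set():
    kept, flags = ex.filter_expressed(part_of([]), pd.DataFrame())
    assert kept == [] and flags.empty


def test_per_homoeolog_filter_requires_all_three():
    t = triad("T1", {"H1": "a", "H2": "b", "H3": "c"})
    tpm = pd.DataFrame({"root": [5.0, 5.0, 0.0]}, index=["a", "b", "c"])
    kept, _ = ex.filter_expressed(part_of([t]), tpm, per_homoeolog=True)
    assert kept == []


# ---------------------------------------------------------------------------
# Standardisation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tpm, expected", [
    ((10, 10, 10), (1 / 3, 1 / 3, 1 / 3)),
    ((30, 10, 10), (0.6, 0.2, 0.2)),
])
def test_standardize_triad(tpm, expected):
    np.testing.assert_allclose(ex.standardize_triad(tpm), expected)


def test_standardize_zero_sum_is_flagged_not_error():
    assert ex.standardize_triad((0, 0, 0)) is None


def test_combine_tissues_mean_then_normalise():
    assert np.allclose(ex.combine_tissues([(10, 0, 0), (0, 10, 0)]),
                       (0.5, 0.5, 0.0))
    one = ex.combine_tissues([(30, 10, 10)])
    np.testing.assert_allclose(one, (0.6, 0.2, 0.2))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("vec, group", [
    ((1 / 3, 1 / 3, 1 / 3), "balanced"),
    ((1, 0, 0), "H1D"),
    ((0, 1, 0), "H2D"),
    ((0, 0, 1), "H3D"),
    ((0, 0.5, 0.5), "H1S"),
    ((0.5, 0, 0.5), "H2S"),
    ((0.5, 0.5, 0), "H3S"),
])
def test_centroids_classify_to_themselves(vec, group):
    a = ex.classify_bias(vec)
    assert a.group == group
    assert a.distances[group] == pytest.approx(0.0, abs=1e-12)


def test_intermediate_point_decided_by_distance():
    # (0.5, 0.25, 0.25): distance to balanced = sqrt(1/24) ~ 0.204,
    # to H1D = sqrt(3/8) ~ 0.612 -> balanced wins
    a = ex.classify_bias((0.5, 0.25, 0.25))
    assert a.group == "balanced"
    assert a.distances["balanced"] == pytest.approx(math.sqrt(1 / 24))
    assert a.distances["H1D"] == pytest.approx(math.sqrt(3 / 8))
    assert a.margin > 0


def test_undefined_vector_is_an_error():
    with pytest.raises(ValueError):
        ex.classify_bias(None)


def test_classification_scale_invariant():
    rng = np.random.default_rng(2)
    for _ in range(50):
        tpm = rng.uniform(0.1, 100.0, size=3)
        g1 = ex.classify_bias(ex.standardize_triad(tpm)).group
        g2 = ex.classify_bias(ex.standardize_triad(tpm * 37.5)).group
        assert g1 == g2


PERM_LABEL = {0: "1", 1: "2", 2: "3"}


def permuted_group(group: str, perm: tuple[int, int, int]) -> str:
    """Group label after relabelling haplotype axes by ``perm``."""
    if group == "balanced":
        return group
    axis = int(group[1]) - 1
    new_axis = perm.index(axis)
    return f"H{PERM_LABEL[new_axis]}{group[2]}"


def test_label_permutation_equivariance():
    """Permuting haplotype axes permutes the assigned labels consistently,
    for all 6 permutations of the three haplotypes."""
    rng = np.random.default_rng(9)
    vectors = [ex.standardize_triad(rng.uniform(0.0, 10.0, 3) + 1e-6)
               for _ in range(40)]
    for perm in itertools.permutations(range(3)):
        for v in vectors:
            base = ex.classify_bias(v).group
            moved = ex.classify_bias(tuple(v[i] for i in perm)).group
            assert moved == permuted_group(base, perm)


# ---------------------------------------------------------------------------
# Summaries and density
# ---------------------------------------------------------------------------

def test_summary_all_balanced():
    rows = [{"triad_id": f"T{i}", "tissue": "root", "group": "balanced"}
            for i in range(100)]
    out = ex.summarize_groups(pd.DataFrame(rows))
    assert out["pct_balanced"].iloc[0] == 100.00
    assert out["n_expressed_triads"].iloc[0] == 100


def test_summary_percentages_sum_to_100(small_sim):
    cfg, _genomes, _models, _hits, truth, counts = small_sim
    tpm = ex.tpm_by_tissue(ex.compute_tpm(counts), counts.tissues)
    triads = [tr.Triad(triad_id=t.triad_id, genes=t.genes,
                       mean_identity=99.0) for t in truth.triads]
    assignments = ex.classify_triads(triads, tpm)
    out = ex.summarize_groups(assignments)
    pct_cols = [c for c in out.columns if c.startswith("pct_")]
    for _, row in out.iterrows():
        assert row[pct_cols].sum() == pytest.approx(100.0, abs=0.05)


def test_empty_tissue_yields_zero_row():
    rows = [{"triad_id": "T1", "tissue": "root", "group": "undefined"}]
    out = ex.summarize_groups(pd.DataFrame(rows))
    assert out["n_expressed_triads"].iloc[0] == 0


def model(gid, chrom, start, end):
    return GeneModel(gene_id=gid, chrom=chrom, strand="+", start=start,
                     end=end)


def test_density_windows_by_midpoint():
    t = tr.Triad(triad_id="T1",
                 genes={"H1": "a", "H2": "b", "H3": "c"},
                 mean_identity=99.0)
    assignments = pd.DataFrame([
        {"triad_id": "T1", "tissue": "combined", "group": "H1D"}])
    models = {
        "a": model("a", "chr1", 149_000, 151_000),  # midpoint 150,000 -> w2
        "b": model("b", "chr1", 99_500, 100_900),   # spans boundary,
        # midpoint 100,200 -> window 2, counted once
        "c": model("c", "chr2", 10, 500),
    }
    out = ex.biased_gene_density(assignments, [t], models, window=100_000)
    rows = {(r["chrom"], r["start"]): r["count"]
            for _, r in out.iterrows()}
    assert rows[("chr1", 100_000)] == 2
    assert rows[("chr2", 0)] == 1
    assert out["count"].sum() == 3
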