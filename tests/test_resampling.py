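import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from introscape import resampling
from introscape.simulate import GenomeAnnotation
from oracles import base_set, density_oracle


def _bg(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# bootstrap of means


def test_bootstrap_identical_groups():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    res = resampling.bootstrap_mean_diff_test(a, a, n_boot=2000, seed=1)
    assert res.observed == 0.0
    assert res.p_value > 0.9


def test_bootstrap_separated_groups():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 50)
    b = rng.normal(5, 1, 50)
    res = resampling.bootstrap_mean_diff_test(a, b, n_boot=20_000, seed=1)
    assert res.p_value <= 1e-4


def test_bootstrap_empty_group_error():
    with pytest.raises(resampling.InputError):
        resampling.bootstrap_mean_diff_test([], [1.0], seed=0)


def test_bootstrap_label_swap_symmetry():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 30)
    b = rng.normal(0.5, 1, 40)
    r1 = resampling.bootstrap_mean_diff_test(a, b, n_boot=5000, seed=7)
    r2 = resampling.bootstrap_mean_diff_test(b, a, n_boot=5000, seed=7)
    assert r1.observed == pytest.approx(-r2.observed)
    # same pool, same seed: the null is label-free, p-values agree closely
    assert abs(r1.p_value - r2.p_value) < 0.02


def test_bootstrap_p_matches_plus_one_formula():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 20)
    b = rng.normal(1, 1, 25)
    res = resampling.bootstrap_mean_diff_test(a, b, n_boot=999, seed=0)
    expected = (1 + np.sum(np.abs(res.null_values) >= abs(res.observed))) / 1000.0
    assert res.p_value == pytest.approx(expected)
    assert res.p_value >= 1.0 / 1000.0  # the +1 correction forbids p = 0


def test_result_json_roundtrip_bit_exact():
    rng = np.random.default_rng(5)
    res = resampling.bootstrap_mean_diff_test(rng.normal(size=10),
                                              rng.normal(size=12),
                                              n_boot=500, seed=9)
    back = resampling.ResamplingResult.from_json(res.to_json())
    assert np.array_equal(back.null_values, res.null_values)
    assert back.observed == res.observed
    assert back.p_value == res.p_value


# ---------------------------------------------------------------------------
# interval shuffling


def test_shuffle_forced_identity():
    template = _bg([("chr1", 100, 300)])
    bg = _bg([("chr1", 100, 300)])
    out = resampling.shuffle_intervals(template, bg, seed=0, n_sets=5)
    for rep in out:
        assert rep.iloc[0].tolist() == ["chr1", 100, 300]


def test_shuffle_preserves_counts_lengths_containment():
    template = _bg([("chr1", 0, 500), ("chr1", 1000, 1300), ("chr2", 0, 200)])
    bg = _bg([("chr1", 0, 10_000), ("chr2", 0, 8_000), ("chr3", 0, 2_000)])
    reps = resampling.shuffle_intervals(template, bg, seed=4, n_sets=50)
    want = sorted((template["end"] - template["start"]).tolist())
    bg_bases = {c: base_set(sub[["start", "end"]].to_numpy())
                for c, sub in bg.groupby("chrom")}
    for rep in reps:
        assert sorted((rep["end"] - rep["start"]).tolist()) == want
        placed = {}
        for _, r in rep.iterrows():
            bases = set(range(r["start"], r["end"]))
            assert bases <= bg_bases[r["chrom"]]
            prev = placed.setdefault(r["chrom"], set())
            assert not (prev & bases)  # intra-replicate non-overlap
            prev |= bases


def test_shuffle_infeasible_length_raises():
    template = _bg([("chr1", 0, 5000)])
    bg = _bg([("chr1", 0, 100)])
    with pytest.raises(resampling.PlacementError):
        resampling.shuffle_intervals(template, bg, seed=0)


def test_shuffle_empty_template():
    out = resampling.shuffle_intervals(_bg([]), _bg([("chr1", 0, 100)]), seed=0,
                                       n_sets=3)
    assert all(len(rep) == 0 for rep in out)


def test_shuffle_start_uniformity_single_region():
    template = _bg([("chr1", 0, 10)])
    bg = _bg([("chr1", 0, 1010)])  # 1001 feasible starts
    reps = resampling.shuffle_intervals(template, bg, seed=11, n_sets=2000)
    starts = np.array([rep["start"].iloc[0] for rep in reps])
    counts, _ = np.histogram(starts, bins=10, range=(0, 1001))
    chi, p = sps.chisquare(counts)
    assert p > 0.01


# ---------------------------------------------------------------------------
# feature density


def _toy_annotation():
    genes = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [100, 600, 50],
        "end": [300, 900, 250],
        "gene_id": ["g1", "g2", "g3"],
        "family": [False, False, False],
        "psg": [True, False, True]})
    cds = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [120, 650, 60],
        "end": [240, 850, 200],
        "gene_id": ["g1", "g2", "g3"]})
    return GenomeAnnotation(genes=genes, cds=cds)


def test_density_no_genes():
    ann = _toy_annotation()
    iv = _bg([("chr1", 2000, 3000)])
    d = resampling.feature_density(iv, ann)
    assert d["genes_per_mb"] == 0.0
    assert d["psg_per_mb"] == 0.0
    assert d["coding_fraction"] == 0.0


def test_density_seventeen_genes_per_mb():
    genes = pd.DataFrame({
        "chrom": ["chr1"] * 17,
        "start": [i * 1000 for i in range(17)],
        "end": [i * 1000 + 500 for i in range(17)],
        "gene_id": [f"g{i}" for i in range(17)],
        "family": [False] * 17, "psg": [False] * 17})
    cds = genes[["chrom", "start", "end", "gene_id"]].copy()
    ann = GenomeAnnotation(genes=genes, cds=cds)
    iv = _bg([("chr1", 0, 1_000_000)])
    d = resampling.feature_density(iv, ann)
    assert d["genes_per_mb"] == pytest.approx(17.0)


def test_density_zero_length_error():
    with pytest.raises(resampling.InputError):
        resampling.feature_density(_bg([]), _toy_annotation())


def test_density_matches_per_base_oracle(rng):
    for _ in range(10):
        genes = []
        cds = []
        for i in range(8):
            chrom = f"chr{1 + i % 2}"
            s = int(rng.integers(0, 3000))
            e = s + int(rng.integers(50, 400))
            genes.append((chrom, s, e, f"g{i}", False, bool(rng.random() < 0.4)))
            cds.append((chrom, s + 10, max(s + 20, e - 10), f"g{i}"))
        ann = GenomeAnnotation(
            genes=pd.DataFrame(genes, columns=["chrom", "start", "end",
                                               "gene_id", "family", "psg"]),
            cds=pd.DataFrame(cds, columns=["chrom", "start", "end", "gene_id"]))
        ivs = []
        for _ in range(4):
            chrom = f"chr{1 + int(rng.integers(2))}"
            s = int(rng.integers(0, 3000))
            ivs.append((chrom, s, s + int(rng.integers(100, 600))))
        iv = _bg(ivs)
        d = resampling.feature_density(iv, ann)
        g_ref, c_ref, p_ref = density_oracle(iv, ann)
        assert d["genes_per_mb"] == pytest.approx(g_ref, abs=1e-10)
        assert d["coding_fraction"] == pytest.approx(c_ref, abs=1e-10)
        assert d["psg_per_mb"] == pytest.approx(p_ref, abs=1e-10)


# ---------------------------------------------------------------------------
# density permutation test


def test_density_permutation_reproducible():
    ann = _toy_annotation()
    tr = _bg([("chr1", 80, 320), ("chr1", 580, 920)])
    bg = _bg([("chr1", 0, 1000), ("chr2", 0, 1000)])
    a = resampling.density_permutation_test(tr, bg, ann, n_boot=50, n_perm=50,
                                            seed=3)
    b = resampling.density_permutation_test(tr, bg, ann, n_boot=50, n_perm=50,
                                            seed=3)
    assert a == b


def test_density_permutation_gene_desert_flag():
    # genes blanket the first 16 kb; tracts planted in the terminal desert
    genes = pd.DataFrame({
        "chrom": ["chr1"] * 40,
        "start": [i * 400 for i in range(40)],
        "end": [i * 400 + 350 for i in range(40)],
        "gene_id": [f"g{i}" for i in range(40)],
        "family": [False] * 40, "psg": [False] * 40})
    cds = genes[["chrom", "start", "end", "gene_id"]].copy()
    ann = GenomeAnnotation(genes=genes, cds=cds)
    tr = _bg([("chr1", 16_000 + i * 600, 16_400 + i * 600) for i in range(6)])
    bg = _bg([("chr1", 0, 20_000)])
    out = resampling.density_permutation_test(tr, bg, ann, n_boot=100,
                                              n_perm=200, seed=5)
    assert out["metrics"]["genes_per_mb"]["outside_null_ci"]


# ---------------------------------------------------------------------------
# gene-family enrichment


def test_enrichment_family_equals_all():
    genes = [f"g{i}" for i in range(30)]
    res = resampling.gene_family_enrichment(genes[:10], genes, genes,
                                            n_draws=200, seed=0)
    assert res.extra["fold"] == pytest.approx(1.0)


def test_enrichment_zero_observed():
    genes = [f"g{i}" for i in range(30)]
    res = resampling.gene_family_enrichment(genes[10:20], genes, ["g0"],
                                            n_draws=200, seed=0)
    assert res.extra["fold"] == 0.0


def test_enrichment_empty_family_error():
    genes = ["a", "b"]
    with pytest.raises(resampling.InputError):
        resampling.gene_family_enrichment(["a"], genes, [], seed=0)


def test_enrichment_null_mean_hypergeometric():
    N, K, k = 200, 30, 25
    genes = [f"g{i}" for i in range(N)]
    family = genes[:K]
    res = resampling.gene_family_enrichment(genes[50:50 + k], genes, family,
                                            n_draws=2000, seed=8)
    expect = k * K / N
    var = k * (K / N) * (1 - K / N) * (N - k) / (N - 1)
    se = np.sqrt(var / 2000)
    assert abs(res.extra["null_mean"] - expect) < 3 * se


# ---------------------------------------------------------------------------
# chromosome absence


def test_absence_two_chromosomes_one_draw():
    res = resampling.chromosome_absence_test({"c1": 20_000, "c2": 20_000},
                                             block_size=10_000, n_draw=1,
                                             n_iter=200, seed=0)
    assert res["freq_ge1_absent"] == 1.0


def test_absence_exhaustive_draw():
    res = resampling.chromosome_absence_test({"c1": 50_000, "c2": 50_000},
                                             block_size=10_000, n_draw=10,
                                             n_iter=100, seed=0)
    assert res["freq_ge1_absent"] == 0.0
    assert res["freq_ge2_absent"] == 0.0


def test_absence_draw_overflow_error():
    with pytest.raises(resampling.InputError):
        resampling.chromosome_absence_test({"c1": 20_000}, block_size=10_000,
                                           n_draw=5, n_iter=10, seed=0)


def test_absence_block_too_small_error():
    with pytest.raises(resampling.InputError):
        resampling.chromosome_absence_test({"c1": 5_000}, block_size=10_000,
                                           n_draw=1, n_iter=10, seed=0)


def test_absence_specific_chromosome_hypergeometric():
    C, per = 5, 20
    lengths = {f"c{i}": per * 10_000 for i in range(C)}
    n_iter, n_draw = 4000, 10
    res = resampling.chromosome_absence_test(lengths, block_size=10_000,
                                             n_draw=n_draw, n_iter=n_iter, seed=2)
    B = C * per
    expect = np.exp(sps.hypergeom.logpmf(0, B, per, n_draw))
    for freq in res["per_chromosome_absent_freq"].values():
        se = np.sqrt(expect * (1 - expect) / n_iter)
        assert abs(freq - expect) < 3.5 * se
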