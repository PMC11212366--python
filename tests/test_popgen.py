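import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introscape import popgen
from oracles import base_set, depth_per_base, ng86_enum

# ---------------------------------------------------------------------------
# genotype masking


def test_mask_gq_boundary():
    calls = np.array([[0], [1]])
    gq = np.array([[29], [30]])
    dp = np.array([[20], [8]])
    rgq = np.array([[40], [30]])
    out = popgen.mask_genotypes_for_dxy(calls, gq, dp, rgq)
    assert out[0, 0] == popgen.MISSING  # GQ 29 fails
    assert out[1, 0] == 1               # all thresholds met exactly: retained


@pytest.mark.parametrize("n", [1000])
def test_mask_count_matches_row_scan(n, rng):
    calls = rng.integers(0, 4, size=(n, 4))
    gq = rng.integers(0, 60, size=(n, 4))
    dp = rng.integers(0, 20, size=(n, 4))
    rgq = rng.integers(0, 60, size=(n, 4))
    out = popgen.mask_genotypes_for_dxy(calls, gq, dp, rgq)
    expected = 0
    for i in range(n):
        for j in range(4):
            if gq[i, j] < 30 or dp[i, j] < 8 or rgq[i, j] < 30:
                expected += 1
    assert int((out == popgen.MISSING).sum()) == expected


# ---------------------------------------------------------------------------
# variant filter


def test_indel_proximity_inclusive_boundary():
    calls = np.zeros((2, 4), dtype=int)
    gq = np.full((2, 4), 60)
    dp = np.full((2, 4), 30)
    is_var = np.array([True, True])
    indel = np.array([3, 4])
    _, keep = popgen.filter_variants(calls, gq, dp, is_var, indel)
    assert not keep[0]  # exactly 3 bp away: dropped
    assert keep[1]      # 4 bp away: kept


def test_variant_filter_masks_low_quality_only_at_variants():
    calls = np.zeros((2, 1), dtype=int)
    gq = np.array([[19], [19]])
    dp = np.array([[30], [30]])
    is_var = np.array([True, False])
    _, _ = popgen.filter_variants(calls, gq, dp, is_var, np.array([99, 99]))
    out, keep = popgen.filter_variants(calls, gq, dp, is_var, np.array([99, 99]))
    assert out[0, 0] == popgen.MISSING
    assert out[1, 0] == 0  # invariant sites untouched by the GQ<20 rule
    assert keep.all()


def test_variant_filter_survivors_match_distance_scan(rng):
    n = 1000
    calls = rng.integers(0, 4, size=(n, 4))
    gq = rng.integers(0, 40, size=(n, 4))
    dp = rng.integers(0, 10, size=(n, 4))
    is_var = rng.random(n) < 0.5
    indel = rng.integers(0, 10, size=n)
    _, keep = popgen.filter_variants(calls, gq, dp, is_var, indel)
    expected = sum(1 for i in range(n) if not (is_var[i] and indel[i] <= 3))
    assert int(keep.sum()) == expected


# ---------------------------------------------------------------------------
# d_XY


def _codes(s):
    return np.array([{"A": 0, "C": 1, "G": 2, "T": 3, "?": popgen.MISSING}[c]
                     for c in s])


def test_dxy_quarter():
    pos = np.arange(4)
    val, n = popgen.dxy(pos, _codes("AAAA"), _codes("AAAT"), 0, 4)
    assert val == pytest.approx(0.25)
    assert n == 4


def test_dxy_identical_zero():
    pos = np.arange(5)
    val, _ = popgen.dxy(pos, _codes("ACGTA"), _codes("ACGTA"), 0, 5)
    assert val == 0.0


def test_dxy_missing_excluded_from_denominator():
    pos = np.arange(4)
    val, n = popgen.dxy(pos, _codes("AC?G"), _codes("ACTG"), 0, 4)
    assert val == 0.0
    assert n == 3


def test_dxy_all_missing_flagged_undefined():
    pos = np.arange(2)
    val, n = popgen.dxy(pos, _codes("??"), _codes("AA"), 0, 2)
    assert np.isnan(val)
    assert n == 0


def test_dxy_empty_interval_error():
    with pytest.raises(popgen.DomainError):
        popgen.dxy(np.arange(3), _codes("AAA"), _codes("AAA"), 5, 5)


def test_dxy_symmetric_and_missing_append_invariant(rng):
    n = 200
    a = rng.integers(0, 4, size=n)
    b = rng.integers(0, 4, size=n)
    pos = np.arange(n)
    v1, _ = popgen.dxy(pos, a, b, 0, n)
    v2, _ = popgen.dxy(pos, b, a, 0, n)
    assert v1 == v2
    # appending fully-missing sites changes nothing
    a2 = np.concatenate([a, np.full(50, popgen.MISSING)])
    b2 = np.concatenate([b, rng.integers(0, 4, size=50)])
    pos2 = np.arange(n + 50)
    v3, _ = popgen.dxy(pos2, a2, b2, 0, n + 50)
    assert v3 == v1


def test_dxy_interval_subsetting():
    pos = np.array([0, 10, 20, 30])
    a = _codes("AAAA")
    b = _codes("TAAA")
    val, n = popgen.dxy(pos, a, b, 5, 35)  # excludes the site at 0
    assert val == 0.0 and n == 3


# ---------------------------------------------------------------------------
# NG86


def test_ng86_identical_sequences():
    est = popgen.ng86_dnds("ATGGCT", "ATGGCT")
    assert est.dn == 0.0 and est.ds == 0.0
    assert est.omega is None
    assert "ds_zero" in est.flags


def test_ng86_fourfold_degenerate_only():
    # GGx glycine: third position fully degenerate; one synonymous change
    a = "GGAGGAGGAGGA"
    b = "GGAGGAGGAGGC"
    est = popgen.ng86_dnds(a, b)
    assert est.dn == 0.0
    assert est.ds > 0.0
    assert est.nd == 0.0 and est.sd == 1.0


def test_ng86_stop_codon_error():
    with pytest.raises(popgen.StopCodonError):
        popgen.ng86_dnds("TAAGCT", "ATGGCT")


def test_ng86_length_errors():
    with pytest.raises(ValueError):
        popgen.ng86_dnds("ATGG", "ATGG")
    with pytest.raises(ValueError):
        popgen.ng86_dnds("ATG", "ATGGCT")


def test_ng86_ambiguity_codons_removed():
    est = popgen.ng86_dnds("ATGNNNGCT", "ATGAAAGCT")
    assert est.n_codons == 2


def test_ng86_matches_enumeration_oracle(rng):
    codons = [c for c in popgen.CODON_TABLE if c not in popgen.STOP_CODONS]
    for _ in range(8):
        a = "".join(rng.choice(codons) for _ in range(20))
        # derive b by mutating a few positions, avoiding stops
        b = list(a)
        for _ in range(10):
            i = int(rng.integers(len(b)))
            b[i] = "ACGT"[int(rng.integers(4))]
            codon = "".join(b[3 * (i // 3):3 * (i // 3) + 3])
            if codon in popgen.STOP_CODONS:
                b[i] = a[i]
        b = "".join(b)
        est = popgen.ng86_dnds(a, b)
        n_ref, s_ref, nd_ref, sd_ref = ng86_enum(a, b)
        assert est.n_sites == pytest.approx(n_ref, abs=1e-10)
        assert est.s_sites == pytest.approx(s_ref, abs=1e-10)
        assert est.nd == pytest.approx(nd_ref, abs=1e-10)
        assert est.sd == pytest.approx(sd_ref, abs=1e-10)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.sampled_from(sorted(set(popgen.CODON_TABLE) - popgen.STOP_CODONS)),
                min_size=1, max_size=15),
       st.lists(st.sampled_from(sorted(set(popgen.CODON_TABLE) - popgen.STOP_CODONS)),
                min_size=1, max_size=15))
def test_ng86_site_counts_sum_to_three_per_codon(ca, cb):
    k = min(len(ca), len(cb))
    est = popgen.ng86_dnds("".join(ca[:k]), "".join(cb[:k]))
    assert est.n_sites + est.s_sites == pytest.approx(3 * est.n_codons, abs=1e-9)


def test_jc_correct_saturation_flag():
    d, sat = popgen.jc_correct(0.8)
    assert sat and np.isnan(d)
    d, sat = popgen.jc_correct(0.1)
    assert not sat and d > 0.1


# ---------------------------------------------------------------------------
# gene filters


def _depth_frame(windows, samples=("O", "P")):
    return pd.DataFrame(windows, columns=["chrom", "start", "end"] + list(samples))


def test_gene_filter_mean_depth_floor():
    d = _depth_frame([("chr1", 0, 300, 9.9, 50.0)])
    res = popgen.gene_filters([(0, 300)], d, "chr1", {})
    assert not res.passed
    assert "mean_depth" in res.reasons


def test_gene_filter_breadth_boundary():
    # 74% of CDS at >=1 read -> fail breadth-1 rule
    d = _depth_frame([("chr1", 0, 74, 20.0, 20.0), ("chr1", 74, 100, 0.0, 20.0)])
    res = popgen.gene_filters([(0, 100)], d, "chr1", {})
    assert "breadth_1x" in res.reasons


def test_gene_filter_stop_codon():
    d = _depth_frame([("chr1", 0, 300, 30.0, 30.0)])
    res = popgen.gene_filters([(0, 9)], d, "chr1", {"O": "ATGTAAGCT"})
    assert "stop_codon" in res.reasons
    ok = popgen.gene_filters([(0, 9)], d, "chr1", {"O": "ATGGCTTAA"})
    assert "stop_codon" not in ok.reasons  # terminal stop is allowed


def test_gene_filter_pass():
    d = _depth_frame([("chr1", 0, 300, 30.0, 25.0)])
    res = popgen.gene_filters([(10, 100)], d, "chr1", {"O": "ATGGCTGCA"})
    assert res.passed and res.reasons == []


def test_gene_filters_match_per_base_oracle(rng):
    for _ in range(50):
        n_win = 12
        win = 50
        rows = []
        for w in range(n_win):
            rows.append(("chr1", w * win, (w + 1) * win,
                         float(rng.choice([0, 2, 12, 30, 120])),
                         float(rng.choice([0, 2, 12, 30, 120]))))
        d = _depth_frame(rows)
        gs = int(rng.integers(0, 200))
        ge = gs + int(rng.integers(60, 300))
        res = popgen.gene_filters([(gs, ge)], d, "chr1", {})
        per_base = depth_per_base(d, "chr1", n_win * win)
        fails = set()
        for s in ("O", "P"):
            arr = per_base[s][gs:ge]
            if arr.mean() < 10 or arr.mean() > 100:
                fails.add("mean_depth")
            if (arr >= 1).mean() < 0.75:
                fails.add("breadth_1x")
            if (arr >= 10).mean() < 0.50:
                fails.add("breadth_10x")
        assert set(res.reasons) == fails


# ---------------------------------------------------------------------------
# gene introgression assignment


def test_gene_fully_inside_tract():
    frac, cds_frac = popgen.assign_gene_introgression(
        (100, 200), [(120, 180)], [(0, 500)])
    assert frac == 1.0 and cds_frac == 1.0


def test_gene_exactly_half_not_introgressed():
    frac, _ = popgen.assign_gene_introgression((0, 100), [], [(0, 50)])
    assert frac == 0.5
    assert not frac > 0.5  # strict > rule: not classified introgressed


def test_gene_fraction_matches_base_oracle(rng):
    for _ in range(25):
        gs = int(rng.integers(0, 500))
        ge = gs + int(rng.integers(10, 400))
        tr = []
        for _ in range(rng.integers(0, 5)):
            s = int(rng.integers(0, 800))
            tr.append((s, s + int(rng.integers(5, 200))))
        frac, _ = popgen.assign_gene_introgression((gs, ge), [], tr)
        gene_bases = set(range(gs, ge))
        covered = gene_bases & base_set(tr)
        assert frac == pytest.approx(len(covered) / len(gene_bases))
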