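"""Interval divergence and pairwise substitution-rate statistics.

d_XY here is the haploid-pair version: for an interval, the fraction of
genotyped sites (invariant sites included) at which both taxa are called
and differ, over the sites at which both are called. Genotype masking and
variant filtering follow strict-inequality semantics: a genotype fails a
filter when its score is strictly below the threshold, so threshold-equal
values are retained; "within 3 bp of an indel" includes exactly 3.

dN/dS uses the Nei-Gojobori (1986) counting method with a Jukes-Cantor
correction as a documented stand-in for an ML codon model; the comparison
consumers make is between gene classes, which counting preserves. The
estimator is pluggable via the ``estimator`` argument of
:func:`gene_rates`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import _intervals

MISSING = -1

CODON_TABLE = {}
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, repeat=3)):
    CODON_TABLE[_a + _b + _c] = _AMINO[_i]
STOP_CODONS = {c for c, aa in CODON_TABLE.items() if aa == "*"}


class SaturationWarning(UserWarning):
    pass


class StopCodonError(ValueError):
    """In-frame stop codon where none is allowed."""


class DomainError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotype masking / filtering


def mask_genotypes_for_dxy(calls: np.ndarray, gq: np.ndarray, dp: np.ndarray,
                           rgq: np.ndarray) -> np.ndarray:
    """Set calls failing GQ < 30, DP < 8 or RGQ < 30 to missing.

    Arrays are (n_sites, n_samples); returns a new call matrix with
    failing genotypes set to ``MISSING``. Sites are always retained.
    """
    calls = np.asarray(calls).copy()
    bad = (np.asarray(gq) < 30) | (np.asarray(dp) < 8) | (np.asarray(rgq) < 30)
    calls[bad] = MISSING
    return calls


def filter_variants(calls: np.ndarray, gq: np.ndarray, dp: np.ndarray,
                    is_variant: np.ndarray, indel_dist: np.ndarray):
    """Variant-site hard filter: mask genotypes with GQ < 20 or DP < 3 and
    drop SNVs within 3 bp (inclusive) of an indel.

    Returns ``(calls, site_keep)`` where ``site_keep`` is a boolean mask of
    surviving sites (invariant sites always survive).
    """
    calls = np.asarray(calls).copy()
    is_variant = np.asarray(is_variant, dtype=bool)
    bad = ((np.asarray(gq) < 20) | (np.asarray(dp) < 3)) & is_variant[:, None]
    calls[bad] = MISSING
    site_keep = ~(is_variant & (np.asarray(indel_dist) <= 3))
    return calls, site_keep


# ---------------------------------------------------------------------------
# d_XY


def dxy(positions: np.ndarray, calls_a: np.ndarray, calls_b: np.ndarray,
        start: int, end: int):
    """Haploid-pair d_XY over [start, end).

    Returns ``(value, n_sites_used)``; ``value`` is ``nan`` (flagged
    undefined) when no site has both taxa called.
    """
    if end <= start:
        raise DomainError("empty interval")
    positions = np.asarray(positions)
    lo = np.searchsorted(positions, start, side="left")
    hi = np.searchsorted(positions, end, side="left")
    a = np.asarray(calls_a)[lo:hi]
    b = np.asarray(calls_b)[lo:hi]
    called = (a != MISSING) & (b != MISSING)
    n = int(called.sum())
    if n == 0:
        return float("nan"), 0
    diffs = int(((a != b) & called).sum())
    return diffs / n, n


# ---------------------------------------------------------------------------
# NG86 dN/dS


@dataclass
class RateEstimate:
    dn: float
    ds: float
    omega: float | None
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int
    saturated_n: bool = False
    saturated_s: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsyn, syn) site counts; changes to stop codons count nonsynonymous
    so every position contributes one full site (N + S = 3 per codon)."""
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for b in "TCAG":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE[alt] == aa and alt not in STOP_CODONS:
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(nonsyn, syn) differences averaged over minimal mutational pathways.

    Pathways passing through a stop codon are discarded; if every pathway
    is blocked, all pathways are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        nd = sd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        results.append((nd, sd, blocked))
    usable = [(nd, sd) for nd, sd, blocked in results if not blocked]
    if not usable:
        usable = [(nd, sd) for nd, sd, _ in results]
    nd = sum(x[0] for x in usable) / len(usable)
    sd = sum(x[1] for x in usable) / len(usable)
    return nd, sd


def jc_correct(p: float) -> tuple[float, bool]:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); flags saturation."""
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0), False


def ng86_dnds(seq_a: str, seq_b: str) -> RateEstimate:
    """Nei-Gojobori (1986) pairwise dN/dS with JC correction.

    Codons containing non-ACGT characters in either sequence are removed
    before counting. An in-frame stop codon raises
    :class:`StopCodonError`. ``omega`` is ``None`` (flagged, not
    fabricated) when dS is zero or undefined.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    if len(seq_a) % 3:
        raise ValueError("aligned length must be divisible by 3")
    codons = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise StopCodonError(f"in-frame stop codon at position {i}")
        codons.append((ca, cb))

    n_sites = s_sites = nd = sd = 0.0
    for ca, cb in codons:
        na, sa = _codon_site_counts(ca)
        nb, sb = _codon_site_counts(cb)
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        d_n, d_s = _pathway_diffs(ca, cb)
        nd += d_n
        sd += d_s

    flags = []
    pn = nd / n_sites if n_sites > 0 else 0.0
    if s_sites > 0:
        ps = sd / s_sites
        dn_val, sat_n = jc_correct(pn)
        ds_val, sat_s = jc_correct(ps)
    else:
        ps = float("nan")
        dn_val, sat_n = jc_correct(pn)
        ds_val, sat_s = float("nan"), False
        flags.append("no_synonymous_sites")
    if sat_n:
        flags.append("saturated_dn")
    if sat_s:
        flags.append("saturated_ds")
    omega = None
    if s_sites > 0 and not (sat_n or sat_s) and ds_val > 0:
        omega = float(dn_val / ds_val)
    elif ds_val == 0:
        flags.append("ds_zero")
    return RateEstimate(dn=float(dn_val), ds=float(ds_val), omega=omega,
                        n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd,
                        n_codons=len(codons), saturated_n=sat_n,
                        saturated_s=sat_s, flags=flags)


# ---------------------------------------------------------------------------
# gene-level operations


@dataclass
class GeneFilterResult:
    passed: bool
    reasons: list[str]


def gene_filters(cds_intervals, depth, chrom: str, sequences: dict[str, str],
                 min_depth: float = 10.0, max_depth: float = 100.0,
                 breadth1_min: float = 0.75, breadth10_min: float = 0.50
                 ) -> GeneFilterResult:
    """Evaluate the four gene-inclusion criteria.

    * any species' mean CDS depth < min_depth or > max_depth -> fail;
    * any species with < breadth1_min of coding bases at >= 1 read -> fail;
    * any species with < breadth10_min of coding bases at >= 10 reads -> fail;
    * a premature stop codon in any provided CDS sequence -> fail.

    ``depth`` is the step-function frame (chrom, start, end, per-species
    columns); ``sequences`` maps taxon name to its CDS nucleotide string.
    All criteria are always evaluated so ``reasons`` is complete.
    """
    from .tracts import mean_depth_over  # local import to avoid cycle

    reasons = []
    cds_intervals = _intervals.merge(cds_intervals)
    if len(cds_intervals) == 0:
        return GeneFilterResult(False, ["no_cds"])

    sub = depth[depth["chrom"] == chrom]
    samples = [c for c in depth.columns if c not in ("chrom", "start", "end")]
    total = _intervals.total_length(cds_intervals)
    means = {s: 0.0 for s in samples}
    ge1 = {s: 0.0 for s in samples}
    ge10 = {s: 0.0 for s in samples}
    for s0, e0 in cds_intervals:
        md = mean_depth_over(depth, chrom, int(s0), int(e0))
        w = (e0 - s0) / total
        for s in samples:
            means[s] += md[s] * w
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(ends, s0, side="right")
        hi = np.searchsorted(starts, e0, side="left")
        ww = (np.minimum(ends[lo:hi], e0) - np.maximum(starts[lo:hi], s0)).astype(float)
        for s in samples:
            vals = sub[s].to_numpy()[lo:hi]
            ge1[s] += float(ww[vals >= 1].sum())
            ge10[s] += float(ww[vals >= 10].sum())

    if any(means[s] < min_depth or means[s] > max_depth for s in samples):
        reasons.append("mean_depth")
    if any(ge1[s] / total < breadth1_min for s in samples):
        reasons.append("breadth_1x")
    if any(ge10[s] / total < breadth10_min for s in samples):
        reasons.append("breadth_10x")
    for name, seq in sequences.items():
        seq = seq.upper()
        n_codons = len(seq) // 3
        for i in range(n_codons - 1):  # final codon may legitimately be a stop
            if seq[3 * i:3 * i + 3] in STOP_CODONS:
                reasons.append("stop_codon")
                break
        else:
            continue
        break
    return GeneFilterResult(passed=not reasons, reasons=reasons)


def assign_gene_introgression(gene_interval, cds_intervals, tract_intervals
                              ) -> tuple[float, float]:
    """(fraction of gene-body bases, fraction of CDS bases) inside tracts.

    The downstream ">half introgressed" classification uses a strict
    ``> 0.5`` on the gene-body fraction.
    """
    gene_frac = _intervals.coverage_fraction([gene_interval], tract_intervals)
    cds_frac = (_intervals.coverage_fraction(cds_intervals, tract_intervals)
                if len(np.asarray(cds_intervals)) else 0.0)
    return gene_frac, cds_frac


def gene_rates(seq_a: str, seq_b: str, estimator=None) -> RateEstimate:
    """Pairwise rate estimate for one gene; estimator defaults to NG86."""
    est = estimator or ng86_dnds
    return est(seq_a, seq_b)
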