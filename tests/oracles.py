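"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written as plain enumeration / per-base recomputation,
deliberately sharing no code path with the package implementations it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------------------
# JC69 pruning oracle: direct summation over internal-node states


def jc_p(t: float) -> np.ndarray:
    e = np.exp(-4.0 * t / 3.0)
    return np.where(np.eye(4, dtype=bool), 0.25 + 0.75 * e, 0.25 - 0.25 * e)


_SISTERS = {0: (2, 3, 1), 1: (2, 1, 3), 2: (1, 3, 2)}


def site_likelihood_enum(column, topology, tip_lengths, internal_length) -> float:
    """Sum over (root, pair-ancestor) state assignments explicitly.

    The rooted tree is root(outgroup, A) with a zero-length branch from the
    root to the ingroup ancestor A, and A(odd, B(sister_i, sister_j)) with
    the internal branch above B.
    """
    si, sj, odd = _SISTERS[topology]
    p = [jc_p(t) for t in tip_lengths]
    p_int = jc_p(internal_length)

    def tip_term(taxon, state):
        obs = column[taxon]
        return 1.0 if obs == 4 else p[taxon][state, obs]

    total = 0.0
    for root in range(4):
        for b in range(4):
            total += (0.25
                      * tip_term(0, root)
                      * tip_term(odd, root)
                      * p_int[root, b]
                      * tip_term(si, b)
                      * tip_term(sj, b))
    return total


# ---------------------------------------------------------------------------
# HMM forward-backward oracle: enumeration over all hidden paths


def fb_enum(emis: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Posterior state probabilities and log-likelihood by summing every
    S^L hidden path explicitly (vectorized but path-exhaustive)."""
    L, S = emis.shape
    paths = np.array(list(itertools.product(range(S), repeat=L)), dtype=np.int64)
    p = pi[paths[:, 0]] * emis[0, paths[:, 0]]
    for t in range(1, L):
        p = p * A[paths[:, t - 1], paths[:, t]] * emis[t, paths[:, t]]
    total = p.sum()
    post = np.stack([np.bincount(paths[:, t], weights=p, minlength=S)
                     for t in range(L)]) / total
    return post, float(np.log(total))


# ---------------------------------------------------------------------------
# NG86 oracle: translation via Biopython, recursive pathway enumeration


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def _syn_fraction(codon: str) -> float:
    """Synonymous one-step changes / 3 per position, stops nonsynonymous."""
    aa = _translate(codon)
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _translate(alt) == aa and _translate(alt) != "*":
                syn += 1
    return syn / 3.0


def _paths(c1: str, c2: str):
    """Recursive enumeration of single-step mutational pathways."""
    if c1 == c2:
        yield []
        return
    for pos in range(3):
        if c1[pos] != c2[pos]:
            step = c1[:pos] + c2[pos] + c1[pos + 1:]
            for rest in _paths(step, c2):
                yield [step] + rest


def ng86_enum(seq_a: str, seq_b: str):
    """(N, S, Nd, Sd) for two aligned coding sequences, NG86 conventions:
    site counts average the two sequences, stop-passing pathways are
    discarded (all pathways used when every one is blocked)."""
    n_sites = s_sites = nd = sd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        fa, fb = _syn_fraction(ca), _syn_fraction(cb)
        s_sites += (fa + fb) / 2.0
        n_sites += 3.0 - (fa + fb) / 2.0
        contributions = []
        for path in _paths(ca, cb):
            codons = [ca] + path
            blocked = any(_translate(c) == "*" for c in codons[1:])
            dn = ds = 0.0
            for prev, cur in zip(codons, codons[1:]):
                if _translate(prev) == _translate(cur):
                    ds += 1.0
                else:
                    dn += 1.0
            contributions.append((dn, ds, blocked))
        usable = [(a, b) for a, b, blk in contributions if not blk]
        if not usable:
            usable = [(a, b) for a, b, _ in contributions]
        if usable:
            nd += sum(x[0] for x in usable) / len(usable)
            sd += sum(x[1] for x in usable) / len(usable)
    return n_sites, s_sites, nd, sd


# ---------------------------------------------------------------------------
# per-base interval / density oracles


def base_set(intervals) -> set[int]:
    out = set()
    for s, e in intervals:
        out.update(range(int(s), int(e)))
    return out


def density_oracle(intervals_df, annotation):
    """(genes_per_mb, coding_fraction, psg_per_mb) by explicit base sets."""
    cover = {}
    total = 0
    for chrom, sub in intervals_df.groupby("chrom"):
        bs = base_set(sub[["start", "end"]].to_numpy())
        cover[str(chrom)] = bs
        total += len(bs)
    n_genes = n_psg = 0
    for _, g in annotation.genes.iterrows():
        bs = cover.get(str(g["chrom"]), set())
        gene_bases = set(range(int(g["start"]), int(g["end"])))
        inside = len(gene_bases & bs)
        if inside > len(gene_bases) / 2.0:
            n_genes += 1
        if g["psg"] and inside > 0:
            n_psg += 1
    coding_in = 0
    for chrom, bs in cover.items():
        cds = annotation.cds[annotation.cds["chrom"] == chrom]
        cds_bases = base_set(cds[["start", "end"]].to_numpy())
        coding_in += len(cds_bases & bs)
    mb = total / 1e6
    return n_genes / mb, coding_in / total, n_psg / mb


def depth_per_base(depth_df, chrom: str, length: int) -> dict[str, np.ndarray]:
    """Expand the step-function depth track to per-base arrays."""
    sub = depth_df[depth_df["chrom"] == chrom]
    samples = [c for c in depth_df.columns if c not in ("chrom", "start", "end")]
    out = {s: np.zeros(length) for s in samples}
    for _, row in sub.iterrows():
        for s in samples:
            out[s][int(row["start"]):int(row["end"])] = row[s]
    return out
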