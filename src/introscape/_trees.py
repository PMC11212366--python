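"""JC69 site likelihoods for rooted four-taxon trees with a fixed outgroup.

Taxon order is (O, P, D, F): outgroup first, then the three ingroup taxa.
The three rooted triplet topologies (outgroup attachment fixed) are
indexed by which ingroup pair is sister:

    topology 0: (O, (P, (D, F)))   — "DF" sisters
    topology 1: (O, (F, (D, P)))   — "DP" sisters
    topology 2: (O, (D, (P, F)))   — "PF" sisters

Base codes: A=0, C=1, G=2, T=3; missing/ambiguous = 4.
"""

from __future__ import annotations

import numpy as np

TAXA = ("O", "P", "D", "F")
N_TOPOLOGIES = 3

# (sister_i, sister_j, odd_ingroup) as indices into the (O,P,D,F) order
TOPOLOGY_SISTERS = {
    0: (2, 3, 1),  # (D, F) sisters, odd P
    1: (2, 1, 3),  # (D, P) sisters, odd F
    2: (1, 3, 2),  # (P, F) sisters, odd D
}

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}


def encode_base(ch: str) -> int:
    """Encode one character; anything outside ACGT maps to missing (4)."""
    return _CODE.get(ch.upper(), 4)


def jc69_matrix(t: float) -> np.ndarray:
    """JC69 transition probability matrix for branch length t (subs/site)."""
    if t < 0:
        raise ValueError(f"negative branch length: {t}")
    e = np.exp(-4.0 * t / 3.0)
    p_same = 0.25 + 0.75 * e
    p_diff = 0.25 - 0.25 * e
    m = np.full((4, 4), p_diff)
    np.fill_diagonal(m, p_same)
    return m


def _tip_partials(codes: np.ndarray) -> np.ndarray:
    """(n,) base codes -> (n, 4) partial likelihoods; missing -> all ones."""
    n = len(codes)
    out = np.zeros((n, 4))
    miss = codes == 4
    out[np.arange(n)[~miss], codes[~miss]] = 1.0
    out[miss] = 1.0
    return out


def site_likelihoods(
    columns: np.ndarray,
    topology: int,
    tip_lengths: np.ndarray,
    internal_length: float,
) -> np.ndarray:
    """Felsenstein-pruning likelihoods of alignment columns under JC69.

    Parameters
    ----------
    columns : (n, 4) int array of base codes in taxon order (O, P, D, F);
        code 4 marks a missing base (marginalized over states).
    topology : rooted triplet topology index (0, 1, 2).
    tip_lengths : length-4 array of terminal branch lengths in (O,P,D,F)
        order, substitutions/site.
    internal_length : branch length above the sister-pair ancestor.

    Returns
    -------
    (n,) array of site likelihoods (uniform root frequencies).
    """
    columns = np.asarray(columns)
    if columns.ndim == 1:
        columns = columns.reshape(1, 4)
    tip_lengths = np.asarray(tip_lengths, dtype=float)
    if tip_lengths.shape != (4,):
        raise ValueError("tip_lengths must have length 4")
    if np.any(tip_lengths < 0) or internal_length < 0:
        raise ValueError("branch lengths must be nonnegative")
    si, sj, odd = TOPOLOGY_SISTERS[topology]

    p_tip = {i: jc69_matrix(tip_lengths[i]) for i in range(4)}
    p_int = jc69_matrix(internal_length)

    tips = {i: _tip_partials(columns[:, i]) for i in range(4)}
    # sister-pair ancestor B, then ingroup ancestor A, then root with O
    lb = (tips[si] @ p_tip[si]) * (tips[sj] @ p_tip[sj])
    la = (tips[odd] @ p_tip[odd]) * (lb @ p_int)
    lroot = (tips[0] @ p_tip[0]) * la
    return 0.25 * lroot.sum(axis=1)


def _evolve(rng: np.random.Generator, states: np.ndarray, t: float) -> np.ndarray:
    """Vectorized JC69 step: P(t) = e*I + (1-e)*(uniform over 4 bases)."""
    e = np.exp(-4.0 * t / 3.0)
    keep = rng.random(len(states)) < e
    fresh = rng.integers(4, size=len(states))
    return np.where(keep, states, fresh)


def simulate_columns(
    rng: np.random.Generator,
    n: int,
    topology: int,
    tip_lengths,
    internal_length: float,
    require_variable: bool = False,
    max_tries: int = 200,
) -> np.ndarray:
    """Draw ``n`` alignment columns (O,P,D,F) under JC69 down the rooted tree.

    With ``require_variable`` invariant columns are rejection-resampled. If
    the tree has (near) zero total length, variable columns may be
    impossible; after ``max_tries`` rounds remaining columns are accepted
    as-is so zero-divergence configurations still terminate.
    """
    tip_lengths = np.asarray(tip_lengths, dtype=float)
    if np.any(tip_lengths < 0) or internal_length < 0:
        raise ValueError("branch lengths must be nonnegative")
    si, sj, odd = TOPOLOGY_SISTERS[topology]

    def draw(m: int) -> np.ndarray:
        root = rng.integers(4, size=m)
        cols = np.empty((m, 4), dtype=np.int64)
        cols[:, 0] = _evolve(rng, root, tip_lengths[0])
        anc_in = root  # zero-length branch from root to ingroup ancestor
        cols[:, odd] = _evolve(rng, anc_in, tip_lengths[odd])
        anc_pair = _evolve(rng, anc_in, internal_length)
        cols[:, si] = _evolve(rng, anc_pair, tip_lengths[si])
        cols[:, sj] = _evolve(rng, anc_pair, tip_lengths[sj])
        return cols

    cols = draw(n)
    if require_variable:
        for _ in range(max_tries):
            invariant = (cols == cols[:, :1]).all(axis=1)
            if not invariant.any():
                break
            cols[invariant] = draw(int(invariant.sum()))
    return cols
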