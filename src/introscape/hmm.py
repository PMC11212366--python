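"""Two-parent-tree phylogenetic HMM with posterior decoding.

Hidden states are (parent tree, gene tree) pairs. There are two parent
trees — "species" (ingroup sisters D,F) and "introgression" (sisters
D,P) — and within each parent the three rooted triplet gene-tree
topologies, giving six states. State ``s`` has parent ``s // 3`` and
topology ``s % 3`` (topology indices as in :mod:`introscape._trees`);
the parent's *concordant* topology is 0 for the species parent and 1 for
the introgression parent.

Transitions: with probability ``parent_switch`` the chain leaves the
current parent and lands on a gene tree drawn from the other parent's
gene-tree weights; otherwise it stays and, with probability
``genetree_switch``, redraws the gene tree from the current parent's
weights. Each parent's weights put ``1 - 2*ils_weight`` on its concordant
topology and ``ils_weight`` on each discordant topology — the discordant
mass is the incomplete-lineage-sorting channel, and it is what makes the
two parent blocks statistically distinguishable.

Emissions are JC69 pruning likelihoods of the SNV column under the
state's topology. Three internal branch lengths are distinguished — one
for each parent's concordant state and one shared by all discordant
(deep-coalescence) states — plus a shared ingroup tip length and an
outgroup tip length.

The HMM steps index SNV columns; physical distance between sites is
ignored. Missing bases are marginalized, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from . import _trees

N_STATES = 6
#: concordant topology per parent (species, introgression)
CONCORDANT = (0, 1)
EMISSION_FLOOR = 1e-300
BRANCH_BOUNDS = (1e-6, 5.0)
#: the discordant states model deep-coalescence genealogies, whose internal
#: branches are short by construction; capping them keeps a parent block from
#: impersonating the other parent's concordant tree through its ILS channel
DISCORDANT_MAX = 0.01


class ParameterError(ValueError):
    """HMM parameters violate their constraints."""


class InputError(ValueError):
    """Unusable alignment input."""


def state_parent(s: int) -> int:
    return s // 3


def state_topology(s: int) -> int:
    return s % 3


@dataclass
class HMMParams:
    """Parameters of the six-state chain.

    branch_lengths keys: ``t_out`` (outgroup tip), ``t_tip`` (shared
    ingroup tip), ``s_species`` / ``s_intro`` (internal branch of each
    parent's concordant state), ``s_discordant`` (shared internal branch
    of the four discordant states).
    """

    parent_switch: float = 0.01
    genetree_switch: float = 0.05
    ils_weight: float = 0.1
    branch_lengths: dict[str, float] = field(default_factory=lambda: {
        "t_out": 0.05, "t_tip": 0.01,
        "s_species": 0.02, "s_intro": 0.02, "s_discordant": 0.005})
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.full(N_STATES, 1.0 / N_STATES))

    def validate(self) -> "HMMParams":
        for name, v in (("parent_switch", self.parent_switch),
                        ("genetree_switch", self.genetree_switch)):
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.ils_weight <= 1.0 / 3.0 + 1e-12:
            raise ParameterError("ils_weight must be in [0, 1/3]")
        for k, v in self.branch_lengths.items():
            if v < 0:
                raise ParameterError(f"branch length {k} must be >= 0, got {v}")
        pi = np.asarray(self.initial_distribution, dtype=float)
        if pi.shape != (N_STATES,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ParameterError("initial distribution must be a length-6 simplex vector")
        A = self.transition_matrix()
        if np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-9):
            raise ParameterError("transition rows must sum to 1 within 1e-9")
        return self

    def topology_weights(self) -> np.ndarray:
        """(2, 3) per-parent gene-tree weights."""
        b = self.ils_weight
        w = np.full((2, 3), b)
        w[0, CONCORDANT[0]] = 1.0 - 2.0 * b
        w[1, CONCORDANT[1]] = 1.0 - 2.0 * b
        return w

    def transition_matrix(self) -> np.ndarray:
        return _transition_matrix(self.parent_switch, self.genetree_switch,
                                  self.ils_weight)

    def state_tree(self, s: int) -> tuple[int, np.ndarray, float]:
        """(topology, tip_lengths[O,P,D,F], internal_length) for state s."""
        bl = self.branch_lengths
        topo = state_topology(s)
        tips = np.array([bl["t_out"], bl["t_tip"], bl["t_tip"], bl["t_tip"]])
        if topo == CONCORDANT[state_parent(s)]:
            internal = bl["s_species"] if state_parent(s) == 0 else bl["s_intro"]
        else:
            internal = bl["s_discordant"]
        return topo, tips, internal


def _transition_matrix(gamma: float, alpha: float, beta: float) -> np.ndarray:
    w = np.full((2, 3), beta)
    w[0, CONCORDANT[0]] = 1.0 - 2.0 * beta
    w[1, CONCORDANT[1]] = 1.0 - 2.0 * beta
    A = np.empty((N_STATES, N_STATES))
    for s in range(N_STATES):
        p, g = s // 3, s % 3
        for s2 in range(N_STATES):
            p2, g2 = s2 // 3, s2 % 3
            if p2 != p:
                A[s, s2] = gamma * w[p2, g2]
            else:
                A[s, s2] = (1.0 - gamma) * (alpha * w[p, g2]
                                            + (1.0 - alpha) * (g2 == g))
    return A


def site_likelihood(column, topology: int, tip_lengths, internal_length: float) -> float:
    """Pruning likelihood of a single (O,P,D,F) column; missing = code 4."""
    return float(_trees.site_likelihoods(
        np.asarray(column, dtype=np.int64).reshape(1, 4),
        topology, np.asarray(tip_lengths, dtype=float), internal_length)[0])


def emission_matrix(patterns: np.ndarray, params: HMMParams,
                    condition_on_variable: bool = False) -> np.ndarray:
    """(n, 6) per-state site likelihoods for the given columns.

    With ``condition_on_variable`` each state's likelihood is divided by
    1 - P(invariant column | state). SNV-only alignments contain no
    invariant columns by construction, and fitting the unconditioned model
    to them drives branch lengths to a degenerate optimum that explains
    the absence of invariant sites instead of the topology signal.
    """
    patterns = np.asarray(patterns, dtype=np.int64)
    invariant = np.tile(np.arange(4, dtype=np.int64)[:, None], (1, 4))
    out = np.empty((len(patterns), N_STATES))
    cache: dict[tuple, np.ndarray] = {}
    for s in range(N_STATES):
        topo, tips, internal = params.state_tree(s)
        key = (topo, internal)
        if key not in cache:
            lik = _trees.site_likelihoods(patterns, topo, tips, internal)
            if condition_on_variable:
                p_inv = _trees.site_likelihoods(invariant, topo, tips, internal).sum()
                lik = lik / max(1.0 - p_inv, 1e-12)
            cache[key] = lik
        out[:, s] = cache[key]
    return np.maximum(out, EMISSION_FLOOR)


# ---------------------------------------------------------------------------
# forward-backward (scaled)


def _fb_numpy(emis: np.ndarray, A: np.ndarray, pi: np.ndarray):
    L, S = emis.shape
    alpha = np.empty((L, S))
    c = np.empty(L)
    a = pi * emis[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, L):
        a = (alpha[t - 1] @ A) * emis[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((L, S))
    beta[L - 1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[t] = (A @ (emis[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    xi_sum = np.zeros((S, S))
    for t in range(L - 1):
        xi_sum += np.outer(alpha[t], emis[t + 1] * beta[t + 1] / c[t + 1]) * A
    return gamma, xi_sum, float(np.log(c).sum())


try:  # numba gives a large speed-up on chromosome-scale chains
    from numba import njit

    @njit(cache=True)
    def _fb_numba(emis, A, pi):  # pragma: no cover - exercised via wrapper
        L, S = emis.shape
        alpha = np.empty((L, S))
        c = np.empty(L)
        tot = 0.0
        for s in range(S):
            alpha[0, s] = pi[s] * emis[0, s]
            tot += alpha[0, s]
        c[0] = tot
        for s in range(S):
            alpha[0, s] /= tot
        for t in range(1, L):
            tot = 0.0
            for s2 in range(S):
                acc = 0.0
                for s in range(S):
                    acc += alpha[t - 1, s] * A[s, s2]
                alpha[t, s2] = acc * emis[t, s2]
                tot += alpha[t, s2]
            c[t] = tot
            for s2 in range(S):
                alpha[t, s2] /= tot
        beta = np.empty((L, S))
        gamma = np.empty((L, S))
        xi_sum = np.zeros((S, S))
        for s in range(S):
            beta[L - 1, s] = 1.0
            gamma[L - 1, s] = alpha[L - 1, s]
        for t in range(L - 2, -1, -1):
            for s in range(S):
                acc = 0.0
                for s2 in range(S):
                    acc += A[s, s2] * emis[t + 1, s2] * beta[t + 1, s2]
                beta[t, s] = acc / c[t + 1]
                gamma[t, s] = alpha[t, s] * beta[t, s]
            for s in range(S):
                w = alpha[t, s] / c[t + 1]
                for s2 in range(S):
                    xi_sum[s, s2] += w * A[s, s2] * emis[t + 1, s2] * beta[t + 1, s2]
        ll = 0.0
        for t in range(L):
            ll += np.log(c[t])
        return gamma, xi_sum, ll

    _FB_IMPL = "numba"
except Exception:  # pragma: no cover
    _fb_numba = None
    _FB_IMPL = "numpy"


def forward_backward(emissions: np.ndarray, params: HMMParams):
    """Posterior state probabilities, expected transition counts, log-lik.

    ``emissions`` is the (L, 6) per-site per-state likelihood matrix.
    Scaling-safe for chains of millions of sites.
    """
    params.validate()
    emis = np.maximum(np.asarray(emissions, dtype=float), EMISSION_FLOOR)
    if emis.ndim != 2 or emis.shape[1] != N_STATES or emis.shape[0] == 0:
        raise InputError("emissions must be a nonempty (L, 6) matrix")
    A = params.transition_matrix()
    pi = np.asarray(params.initial_distribution, dtype=float)
    if _fb_numba is not None:
        gamma, xi_sum, ll = _fb_numba(emis, A, pi)
    else:
        gamma, xi_sum, ll = _fb_numpy(emis, A, pi)
    return gamma, xi_sum, float(ll)


# ---------------------------------------------------------------------------
# Baum-Welch


@dataclass
class PosteriorTrack:
    """Per-SNV-site introgression posterior for one chromosome."""

    chrom: str
    positions: np.ndarray
    introgression_posterior: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.introgression_posterior = np.asarray(self.introgression_posterior,
                                                  dtype=float)
        if len(self.positions) != len(self.introgression_posterior):
            raise ValueError("positions and posteriors length mismatch")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any((self.introgression_posterior < -1e-12)
                  | (self.introgression_posterior > 1 + 1e-12)):
            raise ValueError("posteriors must lie in [0, 1]")
        self.introgression_posterior = np.clip(self.introgression_posterior, 0.0, 1.0)


@dataclass
class RestartResult:
    params: HMMParams
    log_likelihood: float
    ll_trajectory: list[float]
    introgression_posterior: np.ndarray
    n_iterations: int


@dataclass
class FitResult:
    track: PosteriorTrack
    restarts: list[RestartResult]
    averaged: list[int] = field(default_factory=list)  # restart indices used

    @property
    def best(self) -> RestartResult:
        return max(self.restarts, key=lambda r: r.log_likelihood)


def _encode_patterns(codes: np.ndarray):
    """Map (L, 4) columns to unique-pattern indices for fast emission work."""
    key = (codes * np.array([1, 5, 25, 125])).sum(axis=1)
    uniq, idx = np.unique(key, return_inverse=True)
    patterns = np.stack([uniq % 5, uniq // 5 % 5, uniq // 25 % 5, uniq // 125 % 5],
                        axis=1).astype(np.int64)
    return patterns, idx


_BL_KEYS = ("t_out", "t_tip", "s_species", "s_intro", "s_discordant")


def _random_params(rng: np.random.Generator) -> HMMParams:
    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return HMMParams(
        parent_switch=logu(1e-5, 0.5),
        genetree_switch=logu(1e-5, 0.5),
        ils_weight=float(rng.uniform(0.02, 0.32)),
        branch_lengths={
            "t_out": logu(5e-3, 0.3),
            "t_tip": logu(1e-3, 0.1),
            "s_species": logu(1e-3, 0.2),
            "s_intro": logu(1e-3, 0.2),
            "s_discordant": logu(1e-3, DISCORDANT_MAX),
        },
        initial_distribution=np.full(N_STATES, 1.0 / N_STATES),
    )


def _mstep_transitions(params: HMMParams, xi_sum: np.ndarray,
                       maxiter: int) -> HMMParams:
    def neg(x):
        A = _transition_matrix(x[0], x[1], x[2])
        return -float(np.sum(xi_sum * np.log(np.maximum(A, 1e-300))))

    x0 = np.array([params.parent_switch, params.genetree_switch, params.ils_weight])
    x0 = np.clip(x0, [1e-6, 1e-6, 1e-4], [0.999, 0.999, 1 / 3 - 1e-6])
    res = optimize.minimize(neg, x0, method="L-BFGS-B",
                            bounds=[(1e-6, 0.999), (1e-6, 0.999),
                                    (1e-4, 1 / 3 - 1e-6)],
                            options={"maxiter": maxiter})
    if res.fun <= neg(x0):  # generalized EM guard: never move downhill
        return replace(params, parent_switch=float(res.x[0]),
                       genetree_switch=float(res.x[1]),
                       ils_weight=float(res.x[2]))
    return params


def _mstep_emissions(params: HMMParams, patterns: np.ndarray,
                     weights: np.ndarray, maxiter: int) -> HMMParams:
    def neg(x):
        p = replace(params, branch_lengths=dict(zip(_BL_KEYS, map(float, x))))
        emis = emission_matrix(patterns, p, condition_on_variable=True)
        return -float(np.sum(weights * np.log(emis)))

    bounds = [BRANCH_BOUNDS] * 4 + [(BRANCH_BOUNDS[0], DISCORDANT_MAX)]
    x0 = np.array([params.branch_lengths[k] for k in _BL_KEYS])
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter})
    if res.fun <= neg(x0):
        return replace(params, branch_lengths=dict(zip(_BL_KEYS, map(float, res.x))))
    return params


def baum_welch(codes: np.ndarray, params: HMMParams, tol: float = 1e-6,
               max_iter: int = 500, inner_maxiter: int = 25):
    """EM to (local) convergence; returns (params, gamma, trajectory).

    A generalized EM: each M-step is a bounded numeric maximization that is
    rejected if it would lower the expected complete-data objective, so the
    observed-data log-likelihood never decreases.
    """
    codes = np.asarray(codes, dtype=np.int64)
    if codes.ndim != 2 or codes.shape[1] != 4 or len(codes) == 0:
        raise InputError("alignment must contain at least one 4-taxon column")
    patterns, pat_idx = _encode_patterns(codes)
    trajectory = []
    gamma = None
    prev_ll = -np.inf
    for _ in range(max_iter):
        emis = emission_matrix(patterns, params,
                               condition_on_variable=True)[pat_idx]
        gamma, xi_sum, ll = forward_backward(emis, params)
        trajectory.append(ll)
        if ll - prev_ll < tol and len(trajectory) > 1:
            break
        prev_ll = ll
        # M-step
        pi = np.maximum(gamma[0], 1e-12)
        params = replace(params, initial_distribution=pi / pi.sum())
        if len(codes) > 1:
            params = _mstep_transitions(params, xi_sum, inner_maxiter)
        weights = np.zeros((len(patterns), N_STATES))
        np.add.at(weights, pat_idx, gamma)
        params = _mstep_emissions(params, patterns, weights, inner_maxiter)
    return params, gamma, trajectory


def fit(alignment, n_restarts: int = 100, seed: int = 0, tol: float = 1e-6,
        max_iter: int = 500, ll_window: float | None = 30.0) -> FitResult:
    """Run Baum-Welch from ``n_restarts`` random initializations and average
    the per-site introgression posterior across restarts.

    ``alignment`` is a :class:`~introscape.simulate.SiteAlignment` (or any
    object with ``chrom``, ``positions`` and an (L, 4) ``codes`` array).

    Restarts whose final log-likelihood falls more than ``ll_window`` below
    the best restart are excluded from the average (their parameters are
    still reported). At small restart counts a single catastrophically bad
    local optimum would otherwise dominate the averaged posterior; bad
    optima sit hundreds of log-units below the good ones, so the window
    only removes clear failures. Pass ``ll_window=None`` for plain
    averaging over every restart.
    """
    if n_restarts < 1:
        raise InputError("n_restarts must be >= 1")
    codes = np.asarray(alignment.codes, dtype=np.int64)
    if codes.size == 0:
        raise InputError("alignment has zero usable columns")
    restarts = []
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        params0 = _random_params(rng)
        params, gamma, traj = baum_welch(codes, params0, tol=tol, max_iter=max_iter)
        # Escape hatch for a known family of local optima: one parent block
        # ends up owning (almost) all or none of the chain, after which the
        # M-step has no cross-parent mass to pull it out. Refit once from
        # the converged point with the switching parameters reset and keep
        # whichever solution has the higher likelihood.
        occ = float(gamma[:, 3:].sum(axis=1).mean())
        if occ < 0.02 or occ > 0.98:
            bumped = replace(params, parent_switch=0.02,
                             genetree_switch=max(params.genetree_switch, 0.2),
                             ils_weight=min(max(params.ils_weight, 0.05), 1 / 3))
            params2, gamma2, traj2 = baum_welch(codes, bumped, tol=tol,
                                                max_iter=max_iter)
            if traj2[-1] > traj[-1]:
                params, gamma, traj = params2, gamma2, traj2
        intro = gamma[:, 3:].sum(axis=1)
        restarts.append(RestartResult(
            params=params, log_likelihood=traj[-1], ll_trajectory=traj,
            introgression_posterior=intro, n_iterations=len(traj)))
    best_ll = max(r.log_likelihood for r in restarts)
    if ll_window is None:
        used = list(range(len(restarts)))
    else:
        used = [i for i, r in enumerate(restarts)
                if r.log_likelihood >= best_ll - ll_window]
    mean_post = np.mean([restarts[i].introgression_posterior for i in used],
                        axis=0)
    track = PosteriorTrack(chrom=alignment.chrom, positions=alignment.positions,
                           introgression_posterior=mean_post)
    return FitResult(track=track, restarts=restarts, averaged=used)
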