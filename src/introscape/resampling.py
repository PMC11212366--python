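"""Resampling machinery: pooled bootstrap of means, constrained interval
permutation, feature-density nulls, gene-family enrichment, and the
chromosome-absence block test.

Every procedure takes an explicit seed and stores its full null
distribution in the returned :class:`ResamplingResult`, so reports
round-trip bit-exactly. P-values are two-sided with the +1/(n+1)
finite-sample correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _intervals


class PlacementError(RuntimeError):
    """Could not place a shuffled interval inside the background."""


class InputError(ValueError):
    pass


@dataclass
class ResamplingResult:
    observed: float
    null_values: np.ndarray
    p_value: float | None
    ci95: tuple[float, float]
    n_replicates: int
    seed: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) != self.n_replicates:
            raise ValueError("null_values length must equal n_replicates")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")

    def to_json(self) -> str:
        payload = {
            "observed": self.observed,
            "null_values": self.null_values.tolist(),
            "p_value": self.p_value,
            "ci95": list(self.ci95),
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "extra": self.extra,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ResamplingResult":
        d = json.loads(text)
        return cls(observed=d["observed"], null_values=np.asarray(d["null_values"]),
                   p_value=d["p_value"], ci95=tuple(d["ci95"]),
                   n_replicates=d["n_replicates"], seed=d["seed"],
                   extra=d.get("extra", {}))


def _percentile_ci(values: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))


def bootstrap_mean_diff_test(values_a, values_b, n_boot: int = 100_000,
                             seed: int = 0) -> ResamplingResult:
    """Pooled bootstrap comparison of means.

    Both groups are pooled; ``n_boot`` pairs of resamples (sizes |a| and
    |b|, with replacement) are drawn from the pool and their mean
    differences form the null. The two-sided p-value is the corrected
    fraction of null differences at least as extreme as the observed one.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InputError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    observed = float(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    # draw in manageable chunks to bound memory at large n_boot
    null = np.empty(n_boot)
    chunk = max(1, int(5e7 // max(len(a), len(b))))
    for lo in range(0, n_boot, chunk):
        hi = min(lo + chunk, n_boot)
        ra = pool[rng.integers(len(pool), size=(hi - lo, len(a)))].mean(axis=1)
        rb = pool[rng.integers(len(pool), size=(hi - lo, len(b)))].mean(axis=1)
        null[lo:hi] = ra - rb
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_boot + 1.0)
    return ResamplingResult(observed=observed, null_values=null, p_value=float(p),
                            ci95=_percentile_ci(null), n_replicates=n_boot,
                            seed=seed)


# ---------------------------------------------------------------------------
# constrained interval shuffling


def shuffle_intervals(template_intervals: pd.DataFrame,
                      background: pd.DataFrame, seed: int, n_sets: int = 1,
                      max_tries: int = 1000) -> list[pd.DataFrame]:
    """Place intervals of the template's lengths uniformly into background
    regions, without overlap among placed intervals within a replicate.

    Each replicate preserves the count and multiset of template lengths.
    Placement draws a background region with probability proportional to
    its number of feasible start positions, then a uniform start; overlaps
    with already-placed intervals are rejected and retried. Raises
    :class:`PlacementError` (naming the offending length) when a length
    cannot be placed after bounded retries.
    """
    lengths = (template_intervals["end"] - template_intervals["start"]).to_numpy()
    if len(lengths) == 0:
        return [template_intervals.iloc[0:0].copy() for _ in range(n_sets)]
    bg = background[["chrom", "start", "end"]].reset_index(drop=True)
    bg_len = (bg["end"] - bg["start"]).to_numpy()
    if lengths.max() > bg_len.max():
        raise PlacementError(
            f"template length {int(lengths.max())} exceeds the longest "
            f"background region ({int(bg_len.max())})")
    rng = np.random.default_rng(seed)
    out = []
    order = np.argsort(lengths)[::-1]  # place long intervals first
    for _ in range(n_sets):
        for _attempt in range(10):
            placed = _try_place(rng, lengths[order], bg, bg_len, max_tries)
            if placed is not None:
                break
        else:
            raise PlacementError(
                f"could not place an interval of length {int(lengths[order][0])} "
                f"after bounded retries")
        df = pd.DataFrame(placed, columns=["chrom", "start", "end"])
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        out.append(df.sort_values(["chrom", "start"], kind="stable")
                     .reset_index(drop=True))
    return out


def _try_place(rng, lengths, bg, bg_len, max_tries):
    placed_by_chrom: dict[str, list] = {}
    rows = []
    for length in lengths:
        feasible = bg_len - length + 1
        feasible = np.maximum(feasible, 0)
        if feasible.sum() == 0:
            return None
        weights = feasible / feasible.sum()
        ok = False
        for _ in range(max_tries):
            ri = rng.choice(len(bg), p=weights)
            region = bg.iloc[ri]
            start = int(region["start"]) + int(rng.integers(feasible[ri]))
            end = start + int(length)
            existing = placed_by_chrom.get(region["chrom"], [])
            if existing and _intervals.overlaps_any(existing, start, end):
                continue
            placed_by_chrom.setdefault(region["chrom"], []).append((start, end))
            rows.append((region["chrom"], start, end))
            ok = True
            break
        if not ok:
            return None
    return rows


# ---------------------------------------------------------------------------
# feature density


def feature_density(intervals: pd.DataFrame, annotation) -> dict[str, float]:
    """(genes/Mb, coding fraction, PSGs/Mb) of an interval set.

    The gene count uses the ">half of gene-body bases covered" rule; the
    PSG count uses any overlap. Gene and PSG counts are normalized by the
    total interval length in megabases; the coding fraction is coding
    bases in intervals over total interval bases.
    """
    total = 0
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in intervals.groupby("chrom"):
        iv = _intervals.merge(sub[["start", "end"]].to_numpy())
        by_chrom[str(chrom)] = iv
        total += _intervals.total_length(iv)
    if total == 0:
        raise InputError("zero total interval length")

    n_genes = 0
    n_psg = 0
    coding_in = 0
    genes = annotation.genes
    for _, g in genes.iterrows():
        iv = by_chrom.get(str(g["chrom"]))
        if iv is None or len(iv) == 0:
            continue
        frac = _intervals.coverage_fraction([(g["start"], g["end"])], iv)
        if frac > 0.5:
            n_genes += 1
        if g["psg"] and frac > 0.0:
            n_psg += 1
    for chrom, iv in by_chrom.items():
        cds_iv = annotation.cds.loc[annotation.cds["chrom"] == chrom,
                                    ["start", "end"]].to_numpy()
        if len(cds_iv):
            coding_in += _intervals.intersect_length(cds_iv, iv)
    mb = total / 1e6
    return {
        "genes_per_mb": n_genes / mb,
        "coding_fraction": coding_in / total,
        "psg_per_mb": n_psg / mb,
    }


METRICS = ("genes_per_mb", "coding_fraction", "psg_per_mb")


def density_permutation_test(observed_tracts: pd.DataFrame,
                             background: pd.DataFrame, annotation,
                             n_boot: int = 1000, n_perm: int = 1000,
                             seed: int = 0) -> dict:
    """Bootstrap the tract set and compare each density metric to a
    permutation null of same-size interval sets placed in the background.

    Returns, per metric: bootstrap mean and SD over tract pseudoreplicates,
    the null 2.5-97.5 percentile interval, and a CI-exclusion flag.
    """
    rng = np.random.default_rng(seed)
    n = len(observed_tracts)
    if n == 0:
        raise InputError("no observed tracts")
    boot_vals = {m: np.empty(n_boot) for m in METRICS}
    for i in range(n_boot):
        idx = rng.integers(n, size=n)
        rep = observed_tracts.iloc[idx]
        d = feature_density(rep, annotation)
        for m in METRICS:
            boot_vals[m][i] = d[m]
    null_sets = shuffle_intervals(observed_tracts, background,
                                  seed=int(rng.integers(2**31)), n_sets=n_perm)
    null_vals = {m: np.empty(n_perm) for m in METRICS}
    for i, ns in enumerate(null_sets):
        d = feature_density(ns, annotation)
        for m in METRICS:
            null_vals[m][i] = d[m]
    out = {"seed": seed, "n_boot": n_boot, "n_perm": n_perm, "metrics": {}}
    observed = feature_density(observed_tracts, annotation)
    for m in METRICS:
        lo, hi = _percentile_ci(null_vals[m])
        mean = float(boot_vals[m].mean())
        out["metrics"][m] = {
            "observed": float(observed[m]),
            "bootstrap_mean": mean,
            "bootstrap_sd": float(boot_vals[m].std(ddof=1)),
            "null_ci95": [lo, hi],
            "null_values": null_vals[m].tolist(),
            "outside_null_ci": bool(mean < lo or mean > hi),
        }
    return out


def gene_family_enrichment(introgressed_gene_ids, all_gene_ids, family_ids,
                           n_draws: int = 1000, seed: int = 0
                           ) -> ResamplingResult:
    """Fold enrichment of a gene family among introgressed genes versus
    random same-size draws (without replacement) from all genes."""
    introgressed = set(introgressed_gene_ids)
    universe = list(all_gene_ids)
    family = set(family_ids)
    if not family:
        raise InputError("empty family set")
    if not introgressed <= set(universe) or not family <= set(universe):
        raise InputError("introgressed and family genes must be drawn from all genes")
    k = len(introgressed)
    observed = float(len(introgressed & family))
    rng = np.random.default_rng(seed)
    uni = np.asarray(universe, dtype=object)
    fam_mask = np.asarray([g in family for g in universe])
    null = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(len(uni), size=k, replace=False)
        null[i] = fam_mask[idx].sum()
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else float("nan")
    return ResamplingResult(observed=observed, null_values=null, p_value=None,
                            ci95=_percentile_ci(null), n_replicates=n_draws,
                            seed=seed,
                            extra={"fold": fold, "null_mean": null_mean,
                                   "n_introgressed": k, "family_size": len(family)})


def chromosome_absence_test(chromosome_lengths: dict[str, int],
                            block_size: int = 10_000, n_draw: int = 164,
                            n_iter: int = 10_000, seed: int = 0) -> dict:
    """Frequency of iterations in which >= 1 (and >= 2) chromosomes receive
    none of ``n_draw`` blocks sampled without replacement genome-wide.

    Each chromosome contributes floor(length / block_size) blocks.
    """
    names = list(chromosome_lengths)
    blocks = np.array([chromosome_lengths[c] // block_size for c in names])
    if np.any(blocks < 1):
        raise InputError("every chromosome must yield at least one block")
    total = int(blocks.sum())
    if n_draw > total:
        raise InputError(f"n_draw={n_draw} exceeds total blocks ({total})")
    bounds = np.concatenate(([0], np.cumsum(blocks)))
    rng = np.random.default_rng(seed)
    absent_counts = np.empty(n_iter, dtype=np.int64)
    per_chrom_absent = np.zeros(len(names), dtype=np.int64)
    for i in range(n_iter):
        drawn = rng.choice(total, size=n_draw, replace=False)
        hit = np.zeros(len(names), dtype=bool)
        hit[np.unique(np.searchsorted(bounds, drawn, side="right") - 1)] = True
        absent = ~hit
        per_chrom_absent += absent
        absent_counts[i] = absent.sum()
    return {
        "seed": seed,
        "n_iter": n_iter,
        "n_draw": n_draw,
        "block_size": block_size,
        "total_blocks": total,
        "freq_ge1_absent": float((absent_counts >= 1).mean()),
        "freq_ge2_absent": float((absent_counts >= 2).mean()),
        "per_chromosome_absent_freq": {
            names[j]: float(per_chrom_absent[j] / n_iter) for j in range(len(names))
        },
        "absent_counts": absent_counts.tolist(),
    }
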