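"""Tract calling: posterior threshold, depth filter, gap trimming, summaries.

Conventions (applied everywhere):

* a tract is a maximal run of >= 2 consecutive SNV sites whose posterior
  meets the threshold; its span is [first site, last site + 1), half-open;
* depth bounds are inclusive at both ends (a tract fails when any species'
  mean depth is strictly below the floor or strictly above the ceiling);
* the genotype-gap bound is strict (a gap qualifies when the distance
  between adjacent genotyped positions exceeds ``max_gap``); a tract
  overlapping a qualifying gap is split at the gap and the pieces are
  re-checked against the >= 2-site rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _intervals
from .hmm import PosteriorTrack


class CoverageDataError(ValueError):
    """A tract falls outside the domain of the depth track."""


class CorrelationError(ValueError):
    """Correlation undefined (constant input or too few points)."""


@dataclass
class IntrogressionTract:
    chrom: str
    start: int
    end: int
    n_sites: int
    mean_posterior: float
    mean_depth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("tract end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def call_tracts(track: PosteriorTrack, threshold: float) -> list[IntrogressionTract]:
    """Maximal runs of consecutive sites with posterior >= threshold.

    Runs of a single site are discarded. An empty track yields an empty
    list.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    pos = track.positions
    post = track.introgression_posterior
    if len(pos) == 0:
        return []
    ok = post >= threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    out = []
    for lo, hi in edges.reshape(-1, 2):  # [lo, hi) indices of a qualifying run
        if hi - lo < 2:
            continue
        out.append(IntrogressionTract(
            chrom=track.chrom,
            start=int(pos[lo]),
            end=int(pos[hi - 1]) + 1,
            n_sites=int(hi - lo),
            mean_posterior=float(post[lo:hi].mean()),
        ))
    return out


def mean_depth_over(depth: pd.DataFrame, chrom: str, start: int, end: int) -> dict[str, float]:
    """Per-species mean depth over [start, end) from a step-function track."""
    sub = depth[depth["chrom"] == chrom]
    if sub.empty:
        raise CoverageDataError(f"no depth data for {chrom}")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    if start < starts.min() or end > ends.max():
        raise CoverageDataError(
            f"tract {chrom}:{start}-{end} outside depth track domain")
    lo = np.searchsorted(ends, start, side="right")
    hi = np.searchsorted(starts, end, side="left")
    w = (np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)).astype(float)
    samples = [c for c in depth.columns if c not in ("chrom", "start", "end")]
    return {s: float((sub[s].to_numpy()[lo:hi] * w).sum() / w.sum()) for s in samples}


def filter_by_depth(tracts: list[IntrogressionTract], depth: pd.DataFrame,
                    min_depth: float = 5.0, max_depth: float = 100.0
                    ) -> list[IntrogressionTract]:
    """Keep a tract iff every species' mean depth lies in [min, max]."""
    kept = []
    for t in tracts:
        means = mean_depth_over(depth, t.chrom, t.start, t.end)
        t.mean_depth = means
        if all(min_depth <= v <= max_depth for v in means.values()):
            kept.append(t)
    return kept


def genotype_gaps(genotyped_positions: np.ndarray, max_gap: int) -> np.ndarray:
    """(n, 2) half-open intervals strictly between adjacent genotyped
    positions whose distance exceeds ``max_gap``."""
    pos = np.asarray(genotyped_positions, dtype=np.int64)
    if len(pos) < 2:
        return np.zeros((0, 2), dtype=np.int64)
    d = np.diff(pos)
    idx = np.flatnonzero(d > max_gap)
    return np.stack([pos[idx] + 1, pos[idx + 1]], axis=1)


def trim_gaps(tracts: list[IntrogressionTract], track: PosteriorTrack,
              genotyped_positions: np.ndarray, max_gap: int = 25_000
              ) -> list[IntrogressionTract]:
    """Split tracts at inter-genotype gaps > max_gap; re-apply the 2-site rule.

    ``genotyped_positions`` must include invariant sites. Site counts and
    mean posteriors of the split pieces are recomputed from the track.
    """
    gaps = genotype_gaps(genotyped_positions, max_gap)
    if len(gaps) == 0:
        return list(tracts)
    pos = track.positions
    post = track.introgression_posterior
    out = []
    for t in tracts:
        pieces = _intervals.subtract([(t.start, t.end)], gaps)
        if len(pieces) == 1 and pieces[0, 0] == t.start and pieces[0, 1] == t.end:
            out.append(t)
            continue
        for s, e in pieces:
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="left")
            if hi - lo < 2:
                continue
            out.append(IntrogressionTract(
                chrom=t.chrom,
                start=int(pos[lo]), end=int(pos[hi - 1]) + 1,
                n_sites=int(hi - lo),
                mean_posterior=float(post[lo:hi].mean()),
                mean_depth=dict(t.mean_depth),
            ))
    return out


def tracts_to_frame(tracts: list[IntrogressionTract]) -> pd.DataFrame:
    rows = [(t.chrom, t.start, t.end, t.n_sites, t.mean_posterior) for t in tracts]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                     "mean_posterior"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def summarize(tracts: list[IntrogressionTract], chrom_lengths: dict[str, int],
              annotation=None, long_min: int = 10_000) -> dict:
    """Genome-level tract summary.

    Reports tract count, count exceeding ``long_min``, mean/median length,
    percent of genome bases in tracts, percent of CDS bases in tracts
    (when an annotation is given), and per-chromosome percent introgressed.
    """
    lengths = np.array([t.length for t in tracts], dtype=float)
    genome = float(sum(chrom_lengths.values()))
    per_chrom = {}
    for chrom, clen in chrom_lengths.items():
        iv = [(t.start, t.end) for t in tracts if t.chrom == chrom]
        per_chrom[chrom] = 100.0 * _intervals.total_length(iv) / clen if iv else 0.0
    pct_cds = 0.0
    if annotation is not None and len(annotation.cds):
        cds_total = 0
        cds_in = 0
        for chrom in chrom_lengths:
            cds_iv = annotation.cds.loc[annotation.cds["chrom"] == chrom,
                                        ["start", "end"]].to_numpy()
            if len(cds_iv) == 0:
                continue
            tr_iv = [(t.start, t.end) for t in tracts if t.chrom == chrom]
            cds_total += _intervals.total_length(cds_iv)
            if tr_iv:
                cds_in += _intervals.intersect_length(cds_iv, tr_iv)
        pct_cds = 100.0 * cds_in / cds_total if cds_total else 0.0
    total_bases = sum(
        _intervals.total_length([(t.start, t.end) for t in tracts if t.chrom == c])
        for c in chrom_lengths)
    return {
        "n_tracts": len(tracts),
        "n_long": int((lengths > long_min).sum()),
        "mean_length": float(lengths.mean()) if len(lengths) else 0.0,
        "median_length": float(np.median(lengths)) if len(lengths) else 0.0,
        "pct_genome": 100.0 * total_bases / genome if genome else 0.0,
        "pct_cds": pct_cds,
        "per_chrom_pct": per_chrom,
    }


def scaffold_density_correlation(pct_introgressed, genes_per_mb):
    """Spearman rank correlation between per-scaffold percent introgressed
    and per-scaffold gene density; returns (rho, two-sided p)."""
    x = np.asarray(pct_introgressed, dtype=float)
    y = np.asarray(genes_per_mb, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise CorrelationError("need >= 3 paired scaffolds")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
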