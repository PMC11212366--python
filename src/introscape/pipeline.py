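"""Pipeline glue shared by the CLI: alignment construction from genotypes,
species-tree background derivation, and the statistics/report stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _intervals, popgen, resampling, tracts as tractmod
from .config import RunConfig
from .hmm import PosteriorTrack
from .simulate import GenotypeTable, SiteAlignment, resolve_heterozygotes

TAXA = ("O", "P", "D", "F")


def build_alignment(table: GenotypeTable, seed: int) -> SiteAlignment:
    """Hard-filter genotypes and build the pseudo-haploid SNV alignment.

    Variant-site genotypes failing GQ < 20 / DP < 3 are masked, SNVs within
    3 bp of an indel are dropped, and only variant sites at which all four
    samples carry a genotype are kept as alignment columns. The genotyped
    position set (variant + invariant survivors) is retained for gap logic.
    """
    haploid = resolve_heterozygotes(table, seed)
    calls, site_keep = popgen.filter_variants(
        haploid, table.gq, table.dp, table.is_variant, table.indel_dist)
    all_called = (calls != popgen.MISSING).all(axis=1)
    col_mask = table.is_variant & site_keep & all_called
    genotyped = table.positions[site_keep]
    return SiteAlignment(
        chrom=table.chrom,
        positions=table.positions[col_mask],
        codes=calls[col_mask],
        genotyped_positions=genotyped,
    )


def invert_track(track: PosteriorTrack) -> PosteriorTrack:
    return PosteriorTrack(
        chrom=track.chrom, positions=track.positions,
        introgression_posterior=1.0 - track.introgression_posterior)


def species_tree_background(track: PosteriorTrack, threshold: float
                            ) -> list[tractmod.IntrogressionTract]:
    """Maximal >= 2-site runs whose species-tree posterior (1 - introgression
    posterior) meets the threshold; same span convention as tracts."""
    return tractmod.call_tracts(invert_track(track), threshold)


def background_regions(track: PosteriorTrack, depth: pd.DataFrame,
                       genotyped_positions: np.ndarray, cfg: RunConfig
                       ) -> list[tractmod.IntrogressionTract]:
    """Background with the tract filters applied symmetrically."""
    regions = species_tree_background(track, cfg.background_threshold)
    regions = tractmod.filter_by_depth(regions, depth, cfg.min_depth, cfg.max_depth)
    return tractmod.trim_gaps(regions, invert_track(track), genotyped_positions,
                              cfg.max_genotype_gap)


def call_filtered_tracts(track: PosteriorTrack, depth: pd.DataFrame,
                         genotyped_positions: np.ndarray, cfg: RunConfig
                         ) -> list[tractmod.IntrogressionTract]:
    out = tractmod.call_tracts(track, cfg.posterior_threshold)
    out = tractmod.filter_by_depth(out, depth, cfg.min_depth, cfg.max_depth)
    return tractmod.trim_gaps(out, track, genotyped_positions, cfg.max_genotype_gap)


# ---------------------------------------------------------------------------
# d_XY stage


def masked_calls(table: GenotypeTable, seed: int) -> np.ndarray:
    """Pseudo-haploid calls with the divergence-grade genotype mask."""
    haploid = resolve_heterozygotes(table, seed)
    return popgen.mask_genotypes_for_dxy(haploid, table.gq, table.dp, table.rgq)


def interval_dxy(tables: dict[str, GenotypeTable], intervals: pd.DataFrame,
                 taxon_a: str, taxon_b: str, seed: int) -> pd.DataFrame:
    """Per-interval d_XY between two taxa (columns of the quartet)."""
    ia, ib = TAXA.index(taxon_a), TAXA.index(taxon_b)
    cache = {}
    rows = []
    for _, iv in intervals.iterrows():
        chrom = str(iv["chrom"])
        if chrom not in cache:
            t = tables[chrom]
            cache[chrom] = (t.positions, masked_calls(t, seed))
        pos, calls = cache[chrom]
        val, n = popgen.dxy(pos, calls[:, ia], calls[:, ib],
                            int(iv["start"]), int(iv["end"]))
        rows.append((chrom, int(iv["start"]), int(iv["end"]), val, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "dxy", "n_sites"])


# ---------------------------------------------------------------------------
# gene-rate stage


def classify_genes(annotation, tract_df: pd.DataFrame,
                   background_df: pd.DataFrame) -> pd.DataFrame:
    """Per-gene introgression/background base fractions and class labels.

    A gene is "introgressed" when > 1/2 of its gene-body bases fall in
    tracts (strict), "background" when > 1/2 fall in background regions.
    """
    tr_by_chrom = {c: sub[["start", "end"]].to_numpy()
                   for c, sub in tract_df.groupby("chrom")}
    bg_by_chrom = {c: sub[["start", "end"]].to_numpy()
                   for c, sub in background_df.groupby("chrom")}
    rows = []
    for _, g in annotation.genes.iterrows():
        chrom = str(g["chrom"])
        gene_iv = (int(g["start"]), int(g["end"]))
        cds_iv = annotation.cds_intervals(g["gene_id"])
        tr = tr_by_chrom.get(chrom, np.zeros((0, 2), dtype=np.int64))
        bg = bg_by_chrom.get(chrom, np.zeros((0, 2), dtype=np.int64))
        frac_t, frac_t_cds = popgen.assign_gene_introgression(gene_iv, cds_iv, tr)
        frac_b = _intervals.coverage_fraction([gene_iv], bg)
        if frac_t > 0.5:
            label = "introgressed"
        elif frac_b > 0.5:
            label = "background"
        else:
            label = "neither"
        rows.append((g["gene_id"], chrom, gene_iv[0], gene_iv[1], frac_t,
                     frac_t_cds, frac_b, label))
    return pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "start", "end", "frac_tract", "frac_tract_cds",
        "frac_background", "label"])


def extract_cds_sequence(sequences: dict[str, str], taxon: str, chrom: str,
                         cds_intervals: np.ndarray) -> str:
    seq = sequences[f"{taxon}.{chrom}"]
    return "".join(seq[int(s):int(e)] for s, e in cds_intervals)


def gene_rate_table(annotation, classes: pd.DataFrame, depth: pd.DataFrame,
                    sequences: dict[str, str], cfg: RunConfig,
                    taxon_a: str = "O", taxon_b: str = "F") -> pd.DataFrame:
    """Gene filters plus NG86 rates for every classified gene."""
    rows = []
    for _, g in classes.iterrows():
        cds_iv = annotation.cds_intervals(g["gene_id"])
        seq_a = extract_cds_sequence(sequences, taxon_a, g["chrom"], cds_iv)
        seq_b = extract_cds_sequence(sequences, taxon_b, g["chrom"], cds_iv)
        fr = popgen.gene_filters(
            cds_iv, depth, g["chrom"], {taxon_a: seq_a, taxon_b: seq_b},
            min_depth=cfg.gene_min_depth, max_depth=cfg.gene_max_depth,
            breadth1_min=cfg.gene_breadth1_min, breadth10_min=cfg.gene_breadth10_min)
        dn = ds = omega = float("nan")
        if fr.passed:
            try:
                est = popgen.ng86_dnds(seq_a, seq_b)
                dn, ds = est.dn, est.ds
                omega = est.omega if est.omega is not None else float("nan")
            except popgen.StopCodonError:
                fr = popgen.GeneFilterResult(False, fr.reasons + ["stop_codon"])
        rows.append((g["gene_id"], g["label"], fr.passed,
                     ",".join(fr.reasons) or ".", dn, ds, omega))
    return pd.DataFrame(rows, columns=["gene_id", "label", "passed", "reasons",
                                       "dn", "ds", "omega"])


# ---------------------------------------------------------------------------
# report


def tract_frame(tract_list) -> pd.DataFrame:
    return tractmod.tracts_to_frame(tract_list)


def report_table(mean_tests: dict, density_res: dict | None) -> pd.DataFrame:
    """Long-format summary: tract/gene values versus the background.

    ``mean_tests`` maps metric name -> ResamplingResult from
    :func:`introscape.resampling.bootstrap_mean_diff_test`, whose ``extra``
    must carry ``mean_a`` (introgressed) and ``mean_b`` (background).
    """
    rows = []
    for metric, res in mean_tests.items():
        rows.append((metric, f"{res.extra['mean_a']:.6g}",
                     f"{res.extra['mean_b']:.6g}",
                     f"p={res.p_value:.4g}"))
    if density_res is not None:
        for metric in resampling.METRICS:
            m = density_res["metrics"][metric]
            lo, hi = m["null_ci95"]
            rows.append((metric,
                         f"{m['bootstrap_mean']:.6g}±{m['bootstrap_sd']:.6g}",
                         f"{lo:.6g}..{hi:.6g}",
                         "outside_null_ci" if m["outside_null_ci"] else "within_null_ci"))
    return pd.DataFrame(rows, columns=["metric", "introgressed", "background",
                                       "assessment"])
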