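"""Synthetic quartet study generator.

Produces a complete artificial dataset with the statistical structure the
scan pipeline assumes: a genome of one or more chromosomes, SNV alignment
columns for four taxa (outgroup O plus ingroup P, D, F) drawn under JC69
down either the species tree (O,(P,(D,F))) or — inside planted tracts —
the introgression tree (O,(F,(D,P))), diploid genotypes with injected
heterozygosity and per-genotype quality fields, step-function read-depth
tracks, gene models with a multi-copy gene family, and a ground-truth
tract set for recovery tests.

All randomness flows from ``config.seed`` through named substreams (see
:func:`stream`), so every output is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _trees
from .config import BRANCH_KEYS, ConfigError, SimulationConfig

MISSING = 4
#: sentinel distance when no indel exists on the chromosome (VCF-safe)
INDEL_DIST_CAP = 999_999_999


class SizingError(ValueError):
    """Requested features do not fit in the genome."""


def stream(seed: int, tag: str) -> np.random.Generator:
    """Independent, named RNG substream derived from the root seed.

    The substream seed is the first 16 hex digits of sha256("{seed}/{tag}"),
    which is stable across platforms and numpy versions.
    """
    digest = hashlib.sha256(f"{seed}/{tag}".encode()).hexdigest()
    return np.random.default_rng(int(digest[:16], 16))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SiteAlignment:
    """Pseudo-haploid SNV columns for one chromosome.

    ``positions`` are 0-based and strictly increasing; ``codes`` is an
    (n_sites, 4) int array in taxon order (O, P, D, F) with 4 = missing.
    ``genotyped_positions`` additionally includes invariant genotyped sites
    and drives the inter-genotype gap logic downstream.
    """

    chrom: str
    positions: np.ndarray
    codes: np.ndarray
    genotyped_positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.genotyped_positions = np.asarray(self.genotyped_positions, dtype=np.int64)
        if self.codes.shape != (len(self.positions), 4):
            raise ValueError("codes must be (n_sites, 4)")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class TruthSet:
    """Planted tracts and the per-SNV-site parent-tree labels."""

    tracts: pd.DataFrame  # columns: chrom, start, end (half-open, 0-based)
    labels: dict[str, np.ndarray]  # chrom -> bool array over SNV sites

    def tract_intervals(self, chrom: str) -> np.ndarray:
        sub = self.tracts[self.tracts["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy(dtype=np.int64).reshape(-1, 2)


@dataclass
class GenotypeTable:
    """Diploid genotypes with quality fields for one chromosome.

    ``alleles`` is (n_sites, 4 samples, 2 haplotypes) of base codes.
    Quality arrays are (n_sites, 4). ``indel_dist`` is the distance to the
    nearest simulated indel per site (large sentinel when none).
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alleles: np.ndarray
    is_variant: np.ndarray
    gq: np.ndarray
    dp: np.ndarray
    rgq: np.ndarray
    indel_dist: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class GenomeAnnotation:
    """Gene models with CDS sub-intervals, family membership, PSG flags."""

    genes: pd.DataFrame  # chrom, start, end, gene_id, family (bool), psg (bool)
    cds: pd.DataFrame    # chrom, start, end, gene_id

    def gene_interval(self, gene_id: str) -> tuple[str, int, int]:
        row = self.genes[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return str(r["chrom"]), int(r["start"]), int(r["end"])

    def cds_intervals(self, gene_id: str) -> np.ndarray:
        sub = self.cds[self.cds["gene_id"] == gene_id]
        return sub[["start", "end"]].to_numpy(dtype=np.int64).reshape(-1, 2)

    @property
    def family_ids(self) -> list[str]:
        return self.genes.loc[self.genes["family"], "gene_id"].tolist()

    @property
    def psg_ids(self) -> list[str]:
        return self.genes.loc[self.genes["psg"], "gene_id"].tolist()


@dataclass
class SyntheticStudy:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    alignments: list[SiteAlignment]
    truth: TruthSet
    depth: pd.DataFrame  # chrom, start, end, one column per sample
    genotypes: list[GenotypeTable]
    annotation: GenomeAnnotation
    chrom_names: list[str] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# placement helpers


def _chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(len(config.chromosome_lengths))]


def _place_nonoverlapping(rng, lengths: np.ndarray, domain: int, min_gap: int = 0):
    """Place intervals of given lengths uniformly, non-overlapping, in
    [0, domain), keeping at least ``min_gap`` bases between neighbours.

    Returns an (n, 2) array sorted by start. Raises SizingError when the
    footprint does not fit.
    """
    n = len(lengths)
    if n == 0:
        return np.zeros((0, 2), dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    order = rng.permutation(n)
    footprint = int(lengths.sum()) + min_gap * (n - 1)
    free = domain - footprint
    if free < 0:
        raise SizingError(
            f"cannot fit {n} intervals totalling {int(lengths.sum())} bases "
            f"(+gaps) into {domain} bases")
    offsets = np.sort(rng.integers(0, free + 1, size=n))
    shuffled = lengths[order]
    starts = offsets + np.concatenate(([0], np.cumsum(shuffled[:-1] + min_gap)))
    out = np.stack([starts, starts + shuffled], axis=1)
    return out[np.argsort(out[:, 0])]


def _poisson_positions(rng, length: int, mean_spacing: float) -> np.ndarray:
    """Point process with exponential spacings; 0-based positions < length."""
    n_expect = int(length / mean_spacing * 1.3) + 20
    gaps = rng.exponential(mean_spacing, size=n_expect)
    pos = np.cumsum(gaps)
    while pos[-1] < length:
        extra = np.cumsum(rng.exponential(mean_spacing, size=n_expect)) + pos[-1]
        pos = np.concatenate([pos, extra])
    pos = np.unique(pos[pos < length].astype(np.int64))
    return pos


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Generate non-overlapping gene models with CDS sub-intervals.

    Exactly ``family_gene_count`` genes carry the multi-copy family label,
    spread over at least two chromosomes when possible and, within a
    chromosome, separated by more than ``family_min_gap`` bases when the
    chromosome layout allows. ``psg_fraction`` of genes are flagged PSG.
    """
    config.validate()
    rng = stream(config.seed, "annotation")
    chroms = _chrom_names(config)
    lengths = dict(zip(chroms, config.chromosome_lengths))

    if config.gene_count == 0:
        genes = pd.DataFrame(columns=["chrom", "start", "end", "gene_id", "family", "psg"])
        cds = pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])
        return GenomeAnnotation(genes=genes, cds=cds)

    mu = config.gene_length_distribution["mu"]
    sigma = config.gene_length_distribution["sigma"]
    gene_lengths = np.maximum(
        rng.lognormal(mu, sigma, size=config.gene_count).astype(np.int64), 300)

    # apportion genes to chromosomes proportional to length
    total = sum(config.chromosome_lengths)
    weights = np.asarray(config.chromosome_lengths, dtype=float) / total
    assignment = rng.choice(len(chroms), size=config.gene_count, p=weights)

    rows = []
    cds_rows = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        idx = np.where(assignment == ci)[0]
        if len(idx) == 0:
            continue
        placed = _place_nonoverlapping(rng, gene_lengths[idx], lengths[chrom],
                                       min_gap=50)
        for start, end in placed:
            gene_id = f"gene{gid:05d}"
            gid += 1
            rows.append((chrom, int(start), int(end), gene_id))
            cds_rows.extend(_make_cds(rng, chrom, int(start), int(end), gene_id))

    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    genes["family"] = _pick_family(rng, genes, config)
    n_psg = int(round(config.psg_fraction * len(genes)))
    psg = np.zeros(len(genes), dtype=bool)
    psg[rng.choice(len(genes), size=n_psg, replace=False)] = True
    genes["psg"] = psg

    cds = pd.DataFrame(cds_rows, columns=["chrom", "start", "end", "gene_id"])
    cds = cds.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return GenomeAnnotation(genes=genes, cds=cds)


def _make_cds(rng, chrom, start, end, gene_id):
    """1-3 exon CDS covering ~60% of the gene body, total length % 3 == 0."""
    glen = end - start
    n_exons = int(rng.integers(1, 4))
    target = max(30, int(glen * 0.6))
    exon_lens = np.maximum((rng.dirichlet(np.ones(n_exons)) * target).astype(np.int64), 9)
    # trim so the summed CDS length is a codon multiple
    excess = int(exon_lens.sum()) % 3
    if excess:
        exon_lens[-1] -= excess
    if exon_lens.sum() + n_exons > glen:
        exon_lens = np.asarray([max(9, (glen // 2) // 3 * 3)], dtype=np.int64)
        n_exons = 1
    placed = _place_nonoverlapping(rng, exon_lens, glen, min_gap=1)
    return [(chrom, start + int(s), start + int(e), gene_id) for s, e in placed]


def _pick_family(rng, genes: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Greedy spread of family genes across chromosomes with large gaps."""
    flags = np.zeros(len(genes), dtype=bool)
    want = config.family_gene_count
    if want == 0 or len(genes) == 0:
        return flags
    order = rng.permutation(len(genes))
    chosen: list[int] = []

    def compatible(i, relax):
        gi = genes.iloc[i]
        for j in chosen:
            gj = genes.iloc[j]
            if gi["chrom"] != gj["chrom"]:
                continue
            gap = max(gi["start"], gj["start"]) - min(gi["end"], gj["end"])
            if gap <= config.family_min_gap and not relax:
                return False
        return True

    for relax in (False, True):
        for i in order:
            if len(chosen) >= want:
                break
            if i in chosen:
                continue
            if compatible(i, relax):
                chosen.append(int(i))
        if len(chosen) >= want:
            break
    # prefer >= 2 chromosomes when the genome has them
    n_chrom = genes["chrom"].nunique()
    if want >= 2 and n_chrom >= 2:
        used = genes.iloc[chosen]["chrom"].nunique()
        if used < 2:
            other = [i for i in order
                     if genes.iloc[i]["chrom"] != genes.iloc[chosen[0]]["chrom"]]
            if other:
                chosen[-1] = int(other[0])
    flags[chosen[:want]] = True
    return flags


# ---------------------------------------------------------------------------
# quartet simulation


def _branch_arrays(bl: dict[str, float]):
    tips = np.array([bl[k] for k in BRANCH_KEYS[:4]], dtype=float)
    return tips, float(bl["internal"])


def _plant_tracts(rng, config: SimulationConfig, chroms, lengths):
    """Allocate tracts to chromosomes and place them non-overlapping."""
    if config.tract_count == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    mu = config.tract_length_distribution["mu"]
    sigma = config.tract_length_distribution["sigma"]
    weights = np.asarray(config.chromosome_lengths, dtype=float)
    weights = weights / weights.sum()
    assignment = rng.choice(len(chroms), size=config.tract_count, p=weights)
    rows = []
    for ci, chrom in enumerate(chroms):
        n_here = int((assignment == ci).sum())
        if n_here == 0:
            continue
        clen = lengths[chrom]
        tlens = rng.lognormal(mu, sigma, size=n_here).astype(np.int64)
        tlens = np.clip(tlens, 2 * int(config.snv_spacing_mean),
                        max(2, clen // max(1, n_here) - config.min_tract_gap))
        placed = _place_nonoverlapping(rng, tlens, clen,
                                       min_gap=config.min_tract_gap)
        rows.extend((chrom, int(s), int(e)) for s, e in placed)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_quartet(config: SimulationConfig):
    """Simulate the quartet dataset for every chromosome.

    Returns ``(alignments, truth, depth, genotype_tables)``. SNV columns
    inside planted tracts are drawn under the introgression tree, all other
    columns under the species tree; heterozygous diploid genotypes are
    injected at ``heterozygosity_rate`` and randomly resolved to build the
    pseudo-haploid alignments.
    """
    config.validate()
    chroms = _chrom_names(config)
    lengths = dict(zip(chroms, config.chromosome_lengths))

    tracts = _plant_tracts(stream(config.seed, "tracts"), config, chroms, lengths)
    depth = simulate_depth(config)

    sp_tips, sp_internal = _branch_arrays(config.species_tree_branch_lengths)
    in_tips, in_internal = _branch_arrays(config.introgression_tree_branch_lengths)

    alignments = []
    tables = []
    labels = {}
    for chrom in chroms:
        rng = stream(config.seed, f"sites/{chrom}")
        clen = lengths[chrom]
        snv_pos = _poisson_positions(rng, clen, config.snv_spacing_mean)
        inv_pos = _poisson_positions(rng, clen, config.invariant_spacing_mean)
        inv_pos = np.setdiff1d(inv_pos, snv_pos)

        tr = tracts[tracts["chrom"] == chrom][["start", "end"]].to_numpy()
        label = np.zeros(len(snv_pos), dtype=bool)
        for s, e in tr:
            label |= (snv_pos >= s) & (snv_pos < e)
        labels[chrom] = label

        cols = np.empty((len(snv_pos), 4), dtype=np.int64)
        n_sp = int((~label).sum())
        n_in = int(label.sum())
        if n_sp:
            cols[~label] = _trees.simulate_columns(
                rng, n_sp, 0, sp_tips, sp_internal, require_variable=True)
        if n_in:
            cols[label] = _trees.simulate_columns(
                rng, n_in, 1, in_tips, in_internal, require_variable=True)

        table = _build_genotype_table(config, chrom, clen, snv_pos, inv_pos,
                                      cols, depth)
        tables.append(table)
        haploid = resolve_heterozygotes(table, config.seed)
        var_idx = np.where(table.is_variant)[0]
        alignments.append(SiteAlignment(
            chrom=chrom,
            positions=table.positions[var_idx],
            codes=haploid[var_idx],
            genotyped_positions=table.positions,
        ))

    truth = TruthSet(tracts=tracts, labels=labels)
    return alignments, truth, depth, tables


def _build_genotype_table(config, chrom, clen, snv_pos, inv_pos, cols, depth):
    rng = stream(config.seed, f"genotypes/{chrom}")
    positions = np.concatenate([snv_pos, inv_pos])
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    is_variant = np.concatenate(
        [np.ones(len(snv_pos), bool), np.zeros(len(inv_pos), bool)])[order]

    n = len(positions)
    alleles = np.empty((n, 4, 2), dtype=np.int64)
    inv_base = rng.integers(4, size=int((~is_variant).sum()))
    alleles[~is_variant] = inv_base[:, None, None]
    var_rows = np.where(is_variant)[0]
    alleles[var_rows, :, 0] = cols
    alleles[var_rows, :, 1] = cols

    # inject heterozygous genotypes at variant sites
    het = rng.random((len(var_rows), 4)) < config.heterozygosity_rate
    if het.any():
        shift = rng.integers(1, 4, size=int(het.sum()))
        r, c = np.where(het)
        alleles[var_rows[r], c, 1] = (alleles[var_rows[r], c, 0] + shift) % 4

    ref = np.empty(n, dtype=np.int64)
    ref[~is_variant] = alleles[~is_variant, 0, 0]
    # reference allele at variant sites: majority haploid call, ties -> lowest code
    counts = np.stack([(cols == b).sum(axis=1) for b in range(4)], axis=1)
    ref[var_rows] = np.argmax(counts, axis=1)

    gqm = config.gq_model
    gq = np.maximum(rng.normal(gqm["gq_mean"], gqm["gq_sd"], (n, 4)), 0).astype(np.int64)
    rgq = np.maximum(rng.normal(gqm["rgq_mean"], gqm["rgq_sd"], (n, 4)), 0).astype(np.int64)
    dp = _depth_at(depth, chrom, positions, rng)

    indel_pos = _poisson_positions(stream(config.seed, f"indels/{chrom}"),
                                   clen, config.indel_spacing_mean)
    if len(indel_pos):
        j = np.searchsorted(indel_pos, positions)
        left = np.where(j > 0, positions - indel_pos[np.maximum(j - 1, 0)],
                        INDEL_DIST_CAP)
        right = np.where(j < len(indel_pos),
                         indel_pos[np.minimum(j, len(indel_pos) - 1)] - positions,
                         INDEL_DIST_CAP)
        indel_dist = np.minimum(np.minimum(np.abs(left), np.abs(right)),
                                INDEL_DIST_CAP)
    else:
        indel_dist = np.full(n, INDEL_DIST_CAP, dtype=np.int64)

    return GenotypeTable(chrom=chrom, positions=positions, ref=ref,
                         alleles=alleles, is_variant=is_variant,
                         gq=gq, dp=dp, rgq=rgq, indel_dist=indel_dist)


def _depth_at(depth: pd.DataFrame, chrom: str, positions: np.ndarray, rng):
    """Per-sample Poisson read counts around the window depth value."""
    sub = depth[depth["chrom"] == chrom]
    starts = sub["start"].to_numpy()
    samples = [c for c in depth.columns if c not in ("chrom", "start", "end")]
    idx = np.clip(np.searchsorted(starts, positions, side="right") - 1, 0, len(sub) - 1)
    out = np.empty((len(positions), len(samples)), dtype=np.int64)
    for k, s in enumerate(samples):
        lam = sub[s].to_numpy()[idx]
        out[:, k] = rng.poisson(np.maximum(lam, 0.0))
    return out


def simulate_depth(config: SimulationConfig) -> pd.DataFrame:
    """Step-function depth per sample in windows of ``depth_window`` bases."""
    config.validate()
    rng = stream(config.seed, "depth")
    chroms = _chrom_names(config)
    frames = []
    for chrom, clen in zip(chroms, config.chromosome_lengths):
        starts = np.arange(0, clen, config.depth_window, dtype=np.int64)
        ends = np.minimum(starts + config.depth_window, clen)
        cols = {"chrom": chrom, "start": starts, "end": ends}
        for name in ("O", "P", "D", "F"):
            mean, sd = config.depth_model[name]
            cols[name] = np.round(np.maximum(rng.normal(mean, sd, len(starts)), 0.0), 3)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def resolve_heterozygotes(table: GenotypeTable, seed: int) -> np.ndarray:
    """Randomly resolve diploid genotypes to one pseudo-haploid call each.

    Heterozygous genotypes pick either allele with probability 1/2;
    homozygous genotypes are returned unchanged. Deterministic in
    ``seed`` (and the chromosome name, so chromosomes get distinct draws).
    """
    alleles = np.asarray(table.alleles)
    if alleles.ndim != 3 or alleles.shape[2] != 2:
        raise ValueError("expected (n_sites, n_samples, 2) diploid genotypes")
    valid = (alleles >= 0) & (alleles <= MISSING)
    if not valid.all():
        raise ValueError("non-nucleotide allele code in genotype table")
    rng = stream(seed, f"resolve/{table.chrom}")
    pick = rng.integers(2, size=alleles.shape[:2])
    return np.take_along_axis(alleles, pick[:, :, None], axis=2)[:, :, 0]


_STOPS = ("TAA", "TAG", "TGA")


def _robust_codons() -> list[tuple[int, int, int]]:
    """Codons at Hamming distance >= 2 from every stop codon, as base codes.

    Using these as the CDS backbone keeps single-base SNV substitutions
    from creating in-frame stops, so the premature-stop gene filter sees
    realistic (rare) traffic instead of failing every gene.
    """
    import itertools as it

    code = {b: i for i, b in enumerate("ACGT")}
    out = []
    for codon in it.product("ACGT", repeat=3):
        s = "".join(codon)
        if all(sum(a != b for a, b in zip(s, stop)) >= 2 for stop in _STOPS):
            out.append(tuple(code[b] for b in codon))
    return out


def study_sequences(study: SyntheticStudy) -> dict[str, str]:
    """Per-taxon pseudo-haploid chromosome sequences ("{taxon}.{chrom}").

    A random reference background is generated per chromosome and the
    resolved haploid alleles are substituted at genotyped positions, so the
    FASTA is consistent with the VCF and the SNV alignments. CDS regions
    get a stop-robust codon backbone (substituted alleles keep their
    simulated values, so stops remain possible but rare).
    """
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    robust = np.asarray(_robust_codons(), dtype=np.int64)
    out = {}
    taxa = ("O", "P", "D", "F")
    for table in study.genotypes:
        chrom = table.chrom
        clen = study.chrom_lengths[chrom]
        rng = stream(study.config.seed, f"refseq/{chrom}")
        ref = rng.integers(4, size=clen)
        genes = study.annotation.genes
        for gene_id in genes.loc[genes["chrom"] == chrom, "gene_id"]:
            cds_pos = np.concatenate(
                [np.arange(s, e) for s, e in study.annotation.cds_intervals(gene_id)])
            n_codons = len(cds_pos) // 3
            picks = robust[rng.integers(len(robust), size=n_codons)]
            ref[cds_pos[:3 * n_codons]] = picks.reshape(-1)
        ref[table.positions] = table.ref
        haploid = resolve_heterozygotes(table, study.config.seed)
        for t, name in enumerate(taxa):
            seq = ref.copy()
            seq[table.positions] = haploid[:, t]
            out[f"{name}.{chrom}"] = lut[seq].tobytes().decode("ascii")
    return out


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run the full generator: annotation plus quartet data."""
    config.validate()
    annotation = simulate_annotation(config)
    alignments, truth, depth, tables = simulate_quartet(config)
    chroms = _chrom_names(config)
    return SyntheticStudy(
        config=config,
        alignments=alignments,
        truth=truth,
        depth=depth,
        genotypes=tables,
        annotation=annotation,
        chrom_names=chroms,
        chrom_lengths=dict(zip(chroms, config.chromosome_lengths)),
    )
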