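"""Readers and writers for the pipeline's interchange formats.

Internal coordinates are 0-based half-open everywhere; VCF and GFF3 are
converted at the boundary (1-based, closed). Strand is ignored throughout
— every statistic downstream is strand-agnostic. All writers emit
deterministic, newline-terminated text so repeated runs are byte-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._trees import BASES
from .hmm import PosteriorTrack
from .simulate import GenomeAnnotation, GenotypeTable, SiteAlignment

MISSING_CODE = 4


class ParseError(ValueError):
    """Malformed record; message carries the 1-based line number."""


def code_to_base(code: int) -> str:
    return BASES[code] if 0 <= code < 4 else "N"


def base_to_code(ch: str) -> int:
    idx = BASES.find(ch.upper())
    return idx if idx >= 0 else MISSING_CODE


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# VCF


VCF_FORMAT = "GT:GQ:DP:RGQ"


def write_vcf(tables: list[GenotypeTable], sample_names: list[str],
              contig_lengths: dict[str, int], path) -> None:
    """Multi-sample VCF with invariant sites and GQ/DP/RGQ FORMAT fields.

    The distance to the nearest simulated indel travels in INFO/IDIST so
    the variant-filter stage can be exercised without indel records.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscape\n")
        for chrom, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##INFO=<ID=IDIST,Number=1,Type=Integer,'
                 'Description="Distance to nearest indel">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=RGQ,Number=1,Type=Integer,'
                 'Description="Reference genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for table in tables:
            _write_vcf_records(fh, table)


def _write_vcf_records(fh, table: GenotypeTable) -> None:
    for i in range(table.n_sites):
        ref_code = int(table.ref[i])
        alleles = [ref_code]
        gt_fields = []
        for s in range(table.alleles.shape[1]):
            idx = []
            for h in range(2):
                code = int(table.alleles[i, s, h])
                if code == MISSING_CODE:
                    idx.append(".")
                    continue
                if code not in alleles:
                    alleles.append(code)
                idx.append(str(alleles.index(code)))
            gt_fields.append("/".join(idx))
        alt = ",".join(code_to_base(a) for a in alleles[1:]) or "."
        info = f"IDIST={int(table.indel_dist[i])}"
        cols = [table.chrom, str(int(table.positions[i]) + 1), ".",
                code_to_base(ref_code), alt, ".", "PASS", info, VCF_FORMAT]
        for s, gt in enumerate(gt_fields):
            cols.append(f"{gt}:{int(table.gq[i, s])}:{int(table.dp[i, s])}:"
                        f"{int(table.rgq[i, s])}")
        fh.write("\t".join(cols) + "\n")


def read_vcf(path) -> tuple[list[GenotypeTable], list[str], dict[str, int]]:
    """Parse a (plain-text) multi-sample VCF back into genotype tables.

    A hand-rolled line parser is used deliberately: it keeps the
    round-trip fully under this module's control and reports malformed
    records with their line number, which the binary-oriented readers do
    not.
    """
    samples: list[str] = []
    contigs: dict[str, int] = {}
    rows_by_chrom: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if line.startswith("##contig="):
                    body = line[len("##contig=<"):].rstrip(">")
                    fields = dict(kv.split("=", 1) for kv in body.split(","))
                    contigs[fields["ID"]] = int(fields.get("length", 0))
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ParseError(f"line {lineno}: expected >= 10 columns")
            try:
                row = _parse_vcf_record(parts, len(samples))
            except (ValueError, IndexError, KeyError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            rows_by_chrom.setdefault(parts[0], []).append(row)
    tables = []
    for chrom, rows in rows_by_chrom.items():
        pos, ref, alle, var, gq, dp, rgq, idist = map(np.array, zip(*rows))
        tables.append(GenotypeTable(
            chrom=chrom, positions=pos.astype(np.int64),
            ref=ref.astype(np.int64),
            alleles=np.asarray(alle, dtype=np.int64),
            is_variant=var.astype(bool),
            gq=gq.astype(np.int64), dp=dp.astype(np.int64),
            rgq=rgq.astype(np.int64), indel_dist=idist.astype(np.int64)))
    return tables, samples, contigs


def _parse_vcf_record(parts, n_samples):
    pos0 = int(parts[1]) - 1
    ref = base_to_code(parts[3])
    alts = [] if parts[4] == "." else [base_to_code(a) for a in parts[4].split(",")]
    allele_codes = [ref] + alts
    info = dict(kv.split("=", 1) for kv in parts[7].split(";") if "=" in kv)
    idist = int(info.get("IDIST", 999999999))
    fmt_keys = parts[8].split(":")
    alle = np.full((n_samples, 2), MISSING_CODE, dtype=np.int64)
    gq = np.zeros(n_samples, dtype=np.int64)
    dp = np.zeros(n_samples, dtype=np.int64)
    rgq = np.zeros(n_samples, dtype=np.int64)
    for s in range(n_samples):
        fields = dict(zip(fmt_keys, parts[9 + s].split(":")))
        gt = fields["GT"].replace("|", "/").split("/")
        for h in range(2):
            if h < len(gt) and gt[h] != ".":
                alle[s, h] = allele_codes[int(gt[h])]
        gq[s] = int(fields.get("GQ", 0))
        dp[s] = int(fields.get("DP", 0))
        rgq[s] = int(fields.get("RGQ", 0))
    is_variant = len(alts) > 0
    return pos0, ref, alle, is_variant, gq, dp, rgq, idist


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in annotation.genes.iterrows():
            attrs = f"ID={g['gene_id']}"
            if g["family"]:
                attrs += ";gene_family=family1"
            if g["psg"]:
                attrs += ";psg=1"
            fh.write("\t".join([str(g["chrom"]), "introscape", "gene",
                                str(int(g["start"]) + 1), str(int(g["end"])),
                                ".", "+", ".", attrs]) + "\n")
            sub = annotation.cds[annotation.cds["gene_id"] == g["gene_id"]]
            for _, c in sub.iterrows():
                fh.write("\t".join([str(c["chrom"]), "introscape", "CDS",
                                    str(int(c["start"]) + 1), str(int(c["end"])),
                                    ".", "+", "0",
                                    f"Parent={g['gene_id']}"]) + "\n")


def read_gff3(path) -> GenomeAnnotation:
    gene_rows = []
    cds_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"line {lineno}: expected 9 columns")
            chrom, _, kind, start, end, _, _, _, attrs = parts
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if kind == "gene":
                gene_rows.append((chrom, start0, end0, attr["ID"],
                                  "gene_family" in attr, attr.get("psg") == "1"))
            elif kind == "CDS":
                cds_rows.append((chrom, start0, end0, attr["Parent"]))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id",
                                             "family", "psg"])
    cds = pd.DataFrame(cds_rows, columns=["chrom", "start", "end", "gene_id"])
    return GenomeAnnotation(genes=genes, cds=cds)


# ---------------------------------------------------------------------------
# BED


def write_bed(df: pd.DataFrame, path, score_col: str | None = None,
              name_col: str | None = None) -> None:
    """BED3, or BED6 when a score column is given (score = value x 1000)."""
    with open(path, "w") as fh:
        for i, row in df.reset_index(drop=True).iterrows():
            cols = [str(row["chrom"]), str(int(row["start"])), str(int(row["end"]))]
            if score_col is not None:
                name = str(row[name_col]) if name_col else f"region{i}"
                cols += [name, str(int(round(float(row[score_col]) * 1000))), "."]
            fh.write("\t".join(cols) + "\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def validate_bed_frame(df: pd.DataFrame) -> None:
    """Sorted, half-open, positive-length interval frame or ValueError."""
    if np.any(df["end"].to_numpy() <= df["start"].to_numpy()):
        raise ValueError("BED intervals must have end > start")
    for _, sub in df.groupby("chrom"):
        if np.any(np.diff(sub["start"].to_numpy()) < 0):
            raise ValueError("BED intervals must be sorted by start within chrom")


# ---------------------------------------------------------------------------
# depth, posterior track, site table


def write_depth(depth: pd.DataFrame, path) -> None:
    depth.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_depth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_track(tracks: list[PosteriorTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tposterior\n")
        for tr in tracks:
            for p, q in zip(tr.positions, tr.introgression_posterior):
                fh.write(f"{tr.chrom}\t{int(p)}\t{q:.6f}\n")


def read_track(path) -> list[PosteriorTrack]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        out.append(PosteriorTrack(
            chrom=str(chrom),
            positions=sub["pos"].to_numpy(np.int64),
            introgression_posterior=sub["posterior"].to_numpy(float)))
    return out


def write_sites(site_positions: dict[str, np.ndarray], path) -> None:
    """Genotyped positions (invariant sites included) per chromosome."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom, pos in site_positions.items():
            for p in pos:
                fh.write(f"{chrom}\t{int(p)}\n")


def read_sites(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {str(c): sub["pos"].to_numpy(np.int64)
            for c, sub in df.groupby("chrom", sort=False)}


# ---------------------------------------------------------------------------
# PHYLIP alignment + position table


def write_phylip(alignment: SiteAlignment, taxa: list[str], aln_path,
                 pos_path) -> None:
    """Relaxed PHYLIP of the SNV columns plus a chrom/pos table."""
    with open(aln_path, "w") as fh:
        fh.write(f" {len(taxa)} {alignment.n_sites}\n")
        for t, name in enumerate(taxa):
            seq = "".join(code_to_base(c) for c in alignment.codes[:, t])
            fh.write(f"{name}  {seq}\n")
    with open(pos_path, "w") as fh:
        fh.write("chrom\tpos\n")
        for p in alignment.positions:
            fh.write(f"{alignment.chrom}\t{int(p)}\n")


def read_phylip(aln_path, pos_path, genotyped_positions=None) -> SiteAlignment:
    with open(aln_path) as fh:
        header = fh.readline().split()
        n_taxa, n_sites = int(header[0]), int(header[1])
        names = []
        seqs = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                name, seq = line.split()
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            names.append(name)
            seqs.append(seq)
    if len(seqs) != n_taxa or any(len(s) != n_sites for s in seqs):
        raise ParseError("PHYLIP dimensions disagree with header")
    df = pd.read_csv(pos_path, sep="\t")
    chrom = str(df["chrom"].iloc[0])
    positions = df["pos"].to_numpy(np.int64)
    codes = np.stack(
        [np.array([base_to_code(c) for c in s], dtype=np.int64) for s in seqs],
        axis=1)
    gp = positions if genotyped_positions is None else genotyped_positions
    return SiteAlignment(chrom=chrom, positions=positions, codes=codes,
                         genotyped_positions=gp)
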