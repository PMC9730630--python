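"""Readers and writers for the plain-text formats the pipeline exchanges.

Interval files (gene/Alu/repeat BED) are 0-based half-open; site tables
(base counts, SNP catalogue, editing sites, truth tables) use 1-based
positions. The converters live in these readers/writers: in-memory objects
never mix conventions.
"""

from __future__ import annotations

import textwrap
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from .synthdata import (ChromatogramTrace, GeneModel, ReferenceBundle,
                        SyntheticCohort)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, 60)))
            fh.write("\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path), rebuild=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_genes_bed(genes: list[GeneModel], path: str | Path) -> None:
    """BED8: thickStart/thickEnd carry the CDS."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t"
                     f"{g.strand}\t{g.cds_start}\t{g.cds_end}\n")


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            genes.append(GeneModel(chrom=f[0], start=int(f[1]), end=int(f[2]),
                                   name=f[3], strand=f[5],
                                   cds_start=int(f[6]), cds_end=int(f[7])))
    return genes


def write_intervals_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals.to_csv(path, sep="\t", header=False, index=False,
                     columns=["chrom", "start", "end", "name"])


def read_intervals_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "name"],
                         usecols=[0, 1, 2, 3])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    return df


# ---------------------------------------------------------------------------
# SNP catalogue (VCF-like, MAF in INFO)
# ---------------------------------------------------------------------------

def write_snp_vcf(snps: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,'
                 'Description="Minor allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in snps.iterrows():
            fh.write(f"{r['chrom']}\t{r['pos']}\t{r['id']}\t{r['ref']}\t"
                     f"{r['alt']}\t.\t.\tMAF={r['maf']}\n")


def read_snp_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            maf = None
            for kv in f[7].split(";"):
                if kv.startswith("MAF="):
                    maf = kv[4:]
            rows.append((f[0], int(f[1]), f[2], f[3], f[4], maf))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "maf"])
    df["maf"] = pd.to_numeric(df["maf"], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# chromatogram traces
# ---------------------------------------------------------------------------

def write_trace(trace: ChromatogramTrace, path: str | Path) -> None:
    """TSV dialect: index, basecall ('.' between called positions),
    chanA..chanT."""
    call_at = {int(p): b for p, b in zip(trace.base_positions,
                                         trace.basecalls)}
    with open(path, "w") as fh:
        fh.write("index\tbasecall\tchanA\tchanC\tchanG\tchanT\n")
        for i, row in enumerate(trace.intensities):
            b = call_at.get(i, ".")
            vals = "\t".join(f"{v:.3f}" for v in row)
            fh.write(f"{i}\t{b}\t{vals}\n")


def read_trace(path: str | Path) -> ChromatogramTrace:
    df = pd.read_csv(path, sep="\t")
    called = df[df["basecall"] != "."]
    return ChromatogramTrace(
        intensities=df[["chanA", "chanC", "chanG", "chanT"]].to_numpy(float),
        basecalls="".join(called["basecall"]),
        base_positions=called["index"].to_numpy(int),
    )


# ---------------------------------------------------------------------------
# whole-cohort round trip
# ---------------------------------------------------------------------------

COHORT_FILES = {
    "reference": "reference.fa",
    "genes": "genes.bed",
    "alu": "alu.bed",
    "repeats": "simple_repeats.bed",
    "snps": "snps.vcf",
    "conservation": "conservation.tsv",
    "counts": "base_counts.tsv",
    "expression": "expression.tsv",
    "truth_edits": "truth_edits.tsv",
    "truth_levels": "truth_edit_levels.tsv",
    "truth_genotypes": "truth_snp_genotypes.tsv",
    "truth_somatic": "truth_somatic.tsv",
}


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref = cohort.reference
    write_fasta(ref.sequences, out / COHORT_FILES["reference"])
    write_genes_bed(ref.genes, out / COHORT_FILES["genes"])
    write_intervals_bed(ref.alu, out / COHORT_FILES["alu"])
    write_intervals_bed(ref.simple_repeats, out / COHORT_FILES["repeats"])
    write_snp_vcf(ref.snps, out / COHORT_FILES["snps"])
    write_tsv(ref.conservation, out / COHORT_FILES["conservation"])
    write_tsv(cohort.counts, out / COHORT_FILES["counts"])
    write_tsv(cohort.expression, out / COHORT_FILES["expression"])
    write_tsv(cohort.truth.edits, out / COHORT_FILES["truth_edits"])
    write_tsv(cohort.truth.edit_levels, out / COHORT_FILES["truth_levels"])
    write_tsv(cohort.truth.snp_genotypes, out / COHORT_FILES["truth_genotypes"])
    write_tsv(cohort.truth.somatic, out / COHORT_FILES["truth_somatic"])


def read_reference_bundle(indir: str | Path) -> ReferenceBundle:
    d = Path(indir)
    return ReferenceBundle(
        sequences=read_fasta(d / COHORT_FILES["reference"]),
        genes=read_genes_bed(d / COHORT_FILES["genes"]),
        alu=read_intervals_bed(d / COHORT_FILES["alu"]),
        simple_repeats=read_intervals_bed(d / COHORT_FILES["repeats"]),
        snps=read_snp_vcf(d / COHORT_FILES["snps"]),
        conservation=read_tsv(d / COHORT_FILES["conservation"]),
        planted=pd.DataFrame(),
    )
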