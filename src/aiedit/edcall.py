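"""The editing filter cascade: from per-sample RNA variant calls to
cohort-level putative A-to-I editing sites.

Stages, in pipeline order:

1. subtract DNA-supported variants (germline SNPs and somatic SNVs seen in
   exome data of the same patient, either tissue);
2. remove known SNPs (catalogue entries with minor allele frequency
   strictly above 0.001);
3. discard calls inside simple repeats;
4. partition the survivors into Alu and non-Alu groups — Alu calls receive
   no further filtering, the A-to-G dominance there being credible a
   priori;
5. refine the non-Alu group: VAF >= 10% and a unique flanking k-mer in the
   reference (an exact-multiplicity surrogate for a genome-wide similarity
   search; a precomputed mappability BED can be supplied instead).

Surviving calls are collapsed across patients into editing-site records
carrying the strand-aware mismatch class (a reference-forward T>C call in
a minus-strand gene is A-to-G), Alu/repeat/known-database flags,
recurrence, conservation and — inside CDS — the codon-level recoding
consequence (e.g. an A>G at CDS position 22 gives codon 8, Met>Val,
written p.M8V).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from ._util import complement, revcomp
from .synthdata import GeneModel

logger = logging.getLogger(__name__)

MISMATCH_TYPES = tuple(f"{r}-to-{a}" for r in "ACGT" for a in "ACGT" if r != a)


class MissingDNAError(ValueError):
    """RNA calls exist for a patient with no DNA evidence at all."""


# ---------------------------------------------------------------------------
# interval utilities
# ---------------------------------------------------------------------------

def _build_trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for _, row in intervals.iterrows():
        if row["end"] <= row["start"]:
            continue
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]))
    return trees


def _overlaps(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    """Point-in-interval rule for annotation intervals: a site with 1-based
    coordinate ``pos`` is inside [start, end) when start <= pos < end, so
    an interval's exclusive end never captures the site printed at that
    coordinate."""
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlaps(pos))


# ---------------------------------------------------------------------------
# cascade stages
# ---------------------------------------------------------------------------

def dna_support_table(dna_counts: pd.DataFrame,
                      min_alt_reads: int = 2,
                      min_vaf: float = 0.02) -> pd.DataFrame:
    """Scan DNA base counts for any allele with minimal support.

    Returns one row per (sample, chrom, pos, alt) where the exome shows the
    allele at >= ``min_alt_reads`` reads or >= ``min_vaf`` allele fraction
    in either tissue. This is deliberately far more permissive than variant
    calling: any DNA trace of the allele disqualifies the RNA call as an
    editing candidate.
    """
    records = []
    for _, row in dna_counts.iterrows():
        ref = row["ref"]
        for alt in "ACGT":
            if alt == ref:
                continue
            n_alt = int(row[f"{alt}_fwd"]) + int(row[f"{alt}_rev"])
            if n_alt == 0:
                continue
            n_ref = int(row[f"{ref}_fwd"]) + int(row[f"{ref}_rev"]) \
                if ref in "ACGT" else 0
            denom = n_ref + n_alt
            vaf = n_alt / denom if denom else 0.0
            if n_alt >= min_alt_reads or vaf >= min_vaf:
                records.append((row["sample"], row["chrom"], int(row["pos"]),
                                alt, n_alt, vaf))
    return pd.DataFrame(records, columns=["sample", "chrom", "pos", "alt",
                                          "alt_reads", "vaf"])


def subtract_dna_variants(rna_calls: pd.DataFrame,
                          dna_calls: pd.DataFrame,
                          allow_missing_dna: bool = False) -> pd.DataFrame:
    """Remove RNA calls with DNA-level support in the same patient.

    ``dna_calls`` needs columns sample, chrom, pos, alt (either a call
    table or the output of :func:`dna_support_table`); a hit in either
    tissue removes the RNA call. Patients present in RNA but entirely
    absent from DNA raise unless ``allow_missing_dna``.
    """
    if rna_calls.empty or dna_calls.empty:
        if not allow_missing_dna and not rna_calls.empty and dna_calls.empty:
            raise MissingDNAError("no DNA evidence supplied for any patient")
        return rna_calls.copy()
    dna_patients = set(dna_calls["sample"])
    missing = set(rna_calls["sample"]) - dna_patients
    if missing and not allow_missing_dna:
        raise MissingDNAError(
            f"patients with RNA calls but no DNA data: {sorted(missing)}")
    supported = set(zip(dna_calls["sample"], dna_calls["chrom"],
                        dna_calls["pos"], dna_calls["alt"]))
    keys = list(zip(rna_calls["sample"], rna_calls["chrom"],
                    rna_calls["pos"], rna_calls["alt"]))
    keep = np.array([k not in supported for k in keys])
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("DNA subtraction removed %d RNA calls", n_removed)
    return rna_calls.loc[keep].reset_index(drop=True)


def filter_known_snps(calls: pd.DataFrame, snp_catalogue: pd.DataFrame,
                      maf_threshold: float = 0.001) -> pd.DataFrame:
    """Drop calls at catalogue positions with matching alt allele and
    MAF strictly greater than the threshold."""
    if calls.empty or snp_catalogue.empty:
        return calls.copy()
    known = set()
    for _, row in snp_catalogue.iterrows():
        try:
            maf = float(row["maf"])
        except (TypeError, ValueError):
            logger.warning("skipping catalogue entry %s:%s: malformed MAF %r",
                           row.get("chrom"), row.get("pos"), row.get("maf"))
            continue
        if maf > maf_threshold:
            known.add((row["chrom"], int(row["pos"]), row["alt"]))
    keys = list(zip(calls["chrom"], calls["pos"], calls["alt"]))
    keep = np.array([k not in known for k in keys])
    return calls.loc[keep].reset_index(drop=True)


def filter_simple_repeats(calls: pd.DataFrame,
                          repeat_intervals: pd.DataFrame) -> pd.DataFrame:
    """Discard calls overlapping simple-repeat intervals."""
    if calls.empty or repeat_intervals.empty:
        return calls.copy()
    trees = _build_trees(repeat_intervals)
    keep = [not _overlaps(trees, c, p)
            for c, p in zip(calls["chrom"], calls["pos"])]
    return calls.loc[np.array(keep)].reset_index(drop=True)


def partition_alu(calls: pd.DataFrame,
                  alu_intervals: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact, exhaustive split of calls into (Alu, non-Alu)."""
    if calls.empty:
        return calls.copy(), calls.copy()
    trees = _build_trees(alu_intervals)
    in_alu = np.array([_overlaps(trees, c, p)
                       for c, p in zip(calls["chrom"], calls["pos"])])
    return (calls.loc[in_alu].reset_index(drop=True),
            calls.loc[~in_alu].reset_index(drop=True))


def kmer_multiplicity_index(sequences: dict[str, str], k: int = 50) -> Counter:
    """Occurrence counts of every forward-strand k-mer in the reference."""
    index: Counter = Counter()
    for seq in sequences.values():
        for i in range(len(seq) - k + 1):
            index[seq[i:i + k]] += 1
    return index


def flank_is_unique(sequences: dict[str, str], index: Counter,
                    chrom: str, pos: int, k: int = 50) -> bool:
    """True when the k-mer centered on ``pos`` occurs exactly once in the
    genome counting both strands. Sites whose window would run off the
    contig are treated as unique (kept, with a warning)."""
    seq = sequences[chrom]
    lo = pos - 1 - k // 2
    hi = lo + k
    if lo < 0 or hi > len(seq):
        logger.warning("flank window off contig at %s:%d; site retained",
                       chrom, pos)
        return True
    kmer = seq[lo:hi]
    n = index[kmer] + index[revcomp(kmer)]
    if kmer == revcomp(kmer):
        n = index[kmer]
    return n <= 1


def filter_non_alu(non_alu_calls: pd.DataFrame,
                   sequences: dict[str, str] | None = None,
                   min_vaf: float = 0.10,
                   k: int = 50,
                   kmer_index: Counter | None = None,
                   mappability: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stringent refinement of the non-Alu group: VAF >= ``min_vaf`` and a
    flanking sequence unique in the genome. Uniqueness comes from the exact
    k-mer index unless a precomputed low-mappability BED is supplied."""
    if non_alu_calls.empty:
        return non_alu_calls.copy()
    calls = non_alu_calls.loc[non_alu_calls["vaf"] >= min_vaf]
    if mappability is not None and not mappability.empty:
        trees = _build_trees(mappability)
        keep = [not _overlaps(trees, c, p)
                for c, p in zip(calls["chrom"], calls["pos"])]
        calls = calls.loc[np.array(keep)] if len(calls) else calls
    elif sequences is not None:
        if kmer_index is None:
            kmer_index = kmer_multiplicity_index(sequences, k)
        keep = [flank_is_unique(sequences, kmer_index, c, p, k)
                for c, p in zip(calls["chrom"], calls["pos"])]
        calls = calls.loc[np.array(keep)] if len(calls) else calls
    return calls.reset_index(drop=True)


# ---------------------------------------------------------------------------
# classification and annotation
# ---------------------------------------------------------------------------

def classify_mismatch(ref: str, alt: str, gene_strand: str) -> str:
    """Strand-collapsed mismatch class, one of the 12 ordered base pairs.

    ``ref``/``alt`` are given on the forward reference strand; for genes on
    the minus strand both are complemented, so T>C becomes A-to-G.
    """
    if gene_strand not in "+-":
        raise ValueError(f"invalid strand {gene_strand!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if gene_strand == "-":
        ref, alt = complement(ref), complement(alt)
    return f"{ref}-to-{alt}"


@dataclass(frozen=True)
class Consequence:
    region: str                    # "CDS" or "UTR"
    synonymous: bool | None = None
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    cds_pos: int | None = None     # 1-based position within the CDS

    @property
    def hgvs_p(self) -> str | None:
        if self.region != "CDS":
            return None
        return f"p.{self.ref_aa}{self.codon_index}{self.alt_aa}"


def annotate_consequence(chrom: str, pos: int, alt: str, gene: GeneModel,
                         sequences: dict[str, str]) -> Consequence:
    """Codon-level consequence of a substitution inside a gene.

    CDS coordinates count along the transcribed strand; codon_index =
    floor((cds_pos - 1)/3) + 1 and codons are translated with the standard
    genetic code. Sites in the UTR get region="UTR" and no codon fields.
    """
    pos0 = pos - 1
    if not gene.contains(pos0):
        raise ValueError(f"{chrom}:{pos} outside gene {gene.name}")
    if not gene.in_cds(pos0):
        return Consequence(region="UTR")
    seq = sequences[chrom]
    if gene.strand == "+":
        cds_pos = pos0 - gene.cds_start + 1
    else:
        cds_pos = gene.cds_end - pos0
    codon_index = (cds_pos - 1) // 3 + 1
    offset = (cds_pos - 1) % 3
    if gene.strand == "+":
        c0 = gene.cds_start + 3 * (codon_index - 1)
        ref_codon = seq[c0:c0 + 3]
        alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1:]
    else:
        c1 = gene.cds_end - 3 * (codon_index - 1)
        ref_codon = revcomp(seq[c1 - 3:c1])
        alt_codon = ref_codon[:offset] + complement(alt) + ref_codon[offset + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return Consequence(region="CDS", synonymous=(ref_aa == alt_aa),
                       codon_index=codon_index, ref_aa=ref_aa,
                       alt_aa=alt_aa, cds_pos=cds_pos)


# ---------------------------------------------------------------------------
# site assembly and full cascade
# ---------------------------------------------------------------------------

def _gene_lookup(genes: list[GeneModel]):
    def find(chrom: str, pos: int) -> GeneModel | None:
        pos0 = pos - 1
        for g in genes:
            if g.chrom == chrom and g.contains(pos0):
                return g
        return None
    return find


def assemble_editing_sites(calls: pd.DataFrame,
                           genes: list[GeneModel],
                           sequences: dict[str, str],
                           alu_intervals: pd.DataFrame,
                           repeat_intervals: pd.DataFrame,
                           conservation: pd.DataFrame | None = None,
                           db_sites: pd.DataFrame | None = None,
                           recurrence_unit: str = "patient") -> pd.DataFrame:
    """Collapse surviving per-sample calls into cohort editing-site records.

    Recurrence counts distinct patients by default (tumor and normal
    presence of one patient count once); ``recurrence_unit="sample"``
    counts distinct (patient, tissue) samples instead.
    """
    if recurrence_unit not in ("patient", "sample"):
        raise ValueError("recurrence_unit must be 'patient' or 'sample'")
    cols = ["chrom", "pos", "ref", "alt", "gene", "gene_strand",
            "mismatch_type", "is_alu", "in_simple_repeat", "recurrence",
            "db_known", "conservation", "region", "synonymous",
            "codon_index", "ref_aa", "alt_aa", "hgvs_p", "mean_vaf"]
    if calls.empty:
        return pd.DataFrame(columns=cols)
    find_gene = _gene_lookup(genes)
    alu_trees = _build_trees(alu_intervals)
    rep_trees = _build_trees(repeat_intervals)
    cons_map = ({} if conservation is None or conservation.empty
                else {(r["chrom"], int(r["pos"])): float(r["score"])
                      for _, r in conservation.iterrows()})
    db = (set() if db_sites is None or db_sites.empty
          else set(zip(db_sites["chrom"], db_sites["pos"].astype(int))))
    records = []
    for (chrom, pos, alt), grp in calls.groupby(["chrom", "pos", "alt"],
                                                sort=True):
        gene = find_gene(chrom, int(pos))
        if gene is None:
            logger.warning("call at %s:%s outside annotated genes; dropped",
                           chrom, pos)
            continue
        ref = grp["ref"].iloc[0]
        if recurrence_unit == "patient":
            rec = grp["sample"].nunique()
        else:
            rec = grp.groupby(["sample", "tissue"]).ngroups
        cons = annotate_consequence(chrom, int(pos), alt, gene, sequences)
        records.append((
            chrom, int(pos), ref, alt, gene.name, gene.strand,
            classify_mismatch(ref, alt, gene.strand),
            _overlaps(alu_trees, chrom, int(pos)),
            _overlaps(rep_trees, chrom, int(pos)),
            int(rec),
            (chrom, int(pos)) in db,
            cons_map.get((chrom, int(pos)), np.nan),
            cons.region, cons.synonymous, cons.codon_index,
            cons.ref_aa, cons.alt_aa, cons.hgvs_p,
            float(grp["vaf"].mean()),
        ))
    return pd.DataFrame(records, columns=cols)


@dataclass
class CascadeResult:
    sites: pd.DataFrame            # assembled editing-site table
    surviving_calls: pd.DataFrame  # per-sample calls after all filters
    stage_counts: dict[str, int]   # calls remaining after each stage


def run_cascade(rna_calls: pd.DataFrame,
                dna_support: pd.DataFrame,
                snp_catalogue: pd.DataFrame,
                repeat_intervals: pd.DataFrame,
                alu_intervals: pd.DataFrame,
                sequences: dict[str, str],
                genes: list[GeneModel],
                conservation: pd.DataFrame | None = None,
                db_sites: pd.DataFrame | None = None,
                maf_threshold: float = 0.001,
                non_alu_min_vaf: float = 0.10,
                k: int = 50,
                allow_missing_dna: bool = False,
                recurrence_unit: str = "patient") -> CascadeResult:
    """Run the complete filter cascade and assemble editing sites.

    The set-subtraction stages (DNA, known SNPs, simple repeats) commute;
    the Alu partition must precede the stringent non-Alu refinement and
    does so by construction here.
    """
    stage_counts = {"input": len(rna_calls)}
    calls = subtract_dna_variants(rna_calls, dna_support,
                                  allow_missing_dna=allow_missing_dna)
    stage_counts["dna_subtracted"] = len(calls)
    calls = filter_known_snps(calls, snp_catalogue, maf_threshold)
    stage_counts["snp_filtered"] = len(calls)
    calls = filter_simple_repeats(calls, repeat_intervals)
    stage_counts["repeat_filtered"] = len(calls)
    alu_calls, non_alu_calls = partition_alu(calls, alu_intervals)
    stage_counts["alu_group"] = len(alu_calls)
    stage_counts["non_alu_group"] = len(non_alu_calls)
    refined = filter_non_alu(non_alu_calls, sequences, min_vaf=non_alu_min_vaf,
                             k=k)
    stage_counts["non_alu_refined"] = len(refined)
    surviving = pd.concat([alu_calls, refined], ignore_index=True)
    surviving = surviving.sort_values(
        ["chrom", "pos", "alt", "sample", "tissue"]).reset_index(drop=True)
    stage_counts["surviving"] = len(surviving)
    sites = assemble_editing_sites(surviving, genes, sequences, alu_intervals,
                                   repeat_intervals, conservation, db_sites,
                                   recurrence_unit=recurrence_unit)
    stage_counts["sites"] = len(sites)
    return CascadeResult(sites=sites, surviving_calls=surviving,
                         stage_counts=stage_counts)
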