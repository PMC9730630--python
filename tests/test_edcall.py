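"""Filter cascade, strand-aware mismatch classes and recoding annotation."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from aiedit import varcall
from aiedit.edcall import (MissingDNAError, annotate_consequence,
                           assemble_editing_sites, classify_mismatch,
                           dna_support_table, filter_known_snps,
                           filter_non_alu, filter_simple_repeats,
                           partition_alu, run_cascade,
                           subtract_dna_variants)
from aiedit.pipeline import benchmark_against_truth, discover_editing_sites
from aiedit.synthdata import GeneModel
from aiedit._util import complement


def calls_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "sample", "material", "tissue",
                                       "vaf"])


CALL = ("chr1", 100, "A", "G", "P01", "RNA", "tumor", 0.3)


# ---------------------------------------------------------------------------
# DNA subtraction
# ---------------------------------------------------------------------------

def test_dna_supported_rna_call_is_removed():
    rna = calls_df([CALL])
    dna = pd.DataFrame([("P01", "chr1", 100, "G", 5, 0.4)],
                       columns=["sample", "chrom", "pos", "alt",
                                "alt_reads", "vaf"])
    assert subtract_dna_variants(rna, dna).empty


def test_dna_subtraction_requires_matching_patient_and_alt():
    rna = calls_df([CALL])
    other_patient = pd.DataFrame(
        [("P02", "chr1", 100, "G", 5, 0.4), ("P01", "chr1", 999, "G", 5, 0.4)],
        columns=["sample", "chrom", "pos", "alt", "alt_reads", "vaf"])
    out = subtract_dna_variants(rna, other_patient, allow_missing_dna=True)
    assert len(out) == 1


def test_empty_dna_set_is_identity_when_allowed():
    rna = calls_df([CALL])
    out = subtract_dna_variants(rna, pd.DataFrame(), allow_missing_dna=True)
    pd.testing.assert_frame_equal(out, rna)


def test_missing_dna_patient_raises():
    with pytest.raises(MissingDNAError):
        subtract_dna_variants(calls_df([CALL]), pd.DataFrame())


def test_planted_snps_and_somatic_fully_subtracted(clean_cohort):
    """On an error-free cohort, DNA subtraction removes every planted SNP
    and somatic call and no planted edit."""
    ref = clean_cohort.reference
    rna = varcall.call_variants(
        clean_cohort.counts.query("material == 'RNA'"),
        gene_intervals=ref.gene_intervals())
    dna = dna_support_table(clean_cohort.counts.query("material == 'DNA'"))
    out = subtract_dna_variants(rna, dna)
    edits = set(zip(clean_cohort.truth.edits["pos"],
                    clean_cohort.truth.edits["alt"]))
    snp_or_som = set(zip(clean_cohort.truth.snps["pos"],
                         clean_cohort.truth.snps["alt"]))
    snp_or_som |= set(zip(clean_cohort.truth.somatic["pos"],
                          clean_cohort.truth.somatic["alt"]))
    surviving = set(zip(out["pos"], out["alt"]))
    removed = set(zip(rna["pos"], rna["alt"])) - surviving
    assert not (surviving & snp_or_som), "germline/somatic leaked through"
    assert not (removed & edits), "true edits wrongly subtracted"


# ---------------------------------------------------------------------------
# SNP / repeat / Alu filters
# ---------------------------------------------------------------------------

def snp_cat(maf, pos=100, alt="G"):
    return pd.DataFrame([("chr1", pos, "A", alt, maf)],
                        columns=["chrom", "pos", "ref", "alt", "maf"])


def test_common_snp_removed_rare_snp_retained():
    calls = calls_df([CALL])
    assert filter_known_snps(calls, snp_cat(0.10)).empty
    assert len(filter_known_snps(calls, snp_cat(0.0005))) == 1
    # the threshold is a strict greater-than
    assert len(filter_known_snps(calls, snp_cat(0.001))) == 1


def test_snp_filter_requires_matching_alt():
    assert len(filter_known_snps(calls_df([CALL]), snp_cat(0.10, alt="T"))) == 1


def test_empty_catalogue_is_identity():
    calls = calls_df([CALL])
    pd.testing.assert_frame_equal(filter_known_snps(calls, pd.DataFrame()),
                                  calls)


def test_malformed_maf_is_skipped():
    cat = snp_cat("not-a-number")
    assert len(filter_known_snps(calls_df([CALL]), cat)) == 1


def intervals(*triples):
    return pd.DataFrame([(c, s, e, f"iv{i}") for i, (c, s, e)
                         in enumerate(triples)],
                        columns=["chrom", "start", "end", "name"])


def test_repeat_overlap_uses_half_open_intervals():
    rep = intervals(("chr1", 90, 110))
    inside = calls_df([("chr1", 100, "A", "G", "P01", "RNA", "tumor", 0.3)])
    boundary = calls_df([("chr1", 110, "A", "G", "P01", "RNA", "tumor", 0.3)])
    start = calls_df([("chr1", 91, "A", "G", "P01", "RNA", "tumor", 0.3)])
    assert filter_simple_repeats(inside, rep).empty
    assert len(filter_simple_repeats(boundary, rep)) == 1   # end exclusive
    assert filter_simple_repeats(start, rep).empty          # start inclusive
    assert len(filter_simple_repeats(inside, intervals())) == 1


def test_repeat_removal_fraction_matches_overlap_fraction():
    rng = np.random.default_rng(0)
    pos = rng.choice(10_000, size=400, replace=False) + 1
    calls = calls_df([("chr1", int(p), "A", "G", "P01", "RNA", "tumor", 0.3)
                      for p in pos])
    rep = intervals(*[("chr1", s, s + 100) for s in range(0, 10_000, 1000)])
    kept = filter_simple_repeats(calls, rep)
    expected_kept = sum(1 for p in pos if (p - 1) % 1000 >= 100)
    assert len(kept) == expected_kept


def test_alu_partition_is_exact_and_exhaustive():
    alu = intervals(("chr1", 90, 110))
    calls = calls_df([
        ("chr1", 100, "A", "G", "P01", "RNA", "tumor", 0.3),
        ("chr1", 110, "A", "G", "P01", "RNA", "tumor", 0.3),
        ("chr1", 500, "A", "G", "P01", "RNA", "tumor", 0.3),
    ])
    in_alu, out_alu = partition_alu(calls, alu)
    assert list(in_alu["pos"]) == [100]
    assert sorted(out_alu["pos"]) == [110, 500]
    assert len(in_alu) + len(out_alu) == len(calls)


def test_planted_alu_flags_recovered(small_reference):
    planted = small_reference.planted
    calls = calls_df([(r.chrom, r.pos, r.ref, r.alt, "P01", "RNA", "tumor", 0.3)
                      for r in planted.itertuples()])
    in_alu, out_alu = partition_alu(calls, small_reference.alu)
    assert set(in_alu["pos"]) == set(planted.loc[planted["in_alu"], "pos"])
    assert set(out_alu["pos"]) == set(planted.loc[~planted["in_alu"], "pos"])


# ---------------------------------------------------------------------------
# non-Alu stringent filtering
# ---------------------------------------------------------------------------

def test_dual_vaf_thresholds_alu_vs_non_alu():
    """A 7% VAF call survives in Alu but not outside it."""
    alu = intervals(("chr1", 90, 110))
    seqs = {"chr1": "".join(np.random.default_rng(1).choice(list("ACGT"),
                                                            1000))}
    calls = calls_df([
        ("chr1", 100, "A", "G", "P01", "RNA", "tumor", 0.07),
        ("chr1", 500, "A", "G", "P01", "RNA", "tumor", 0.07),
        ("chr1", 600, "A", "G", "P01", "RNA", "tumor", 0.30),
    ])
    in_alu, out_alu = partition_alu(calls, alu)
    refined = filter_non_alu(out_alu, seqs)
    survivors = pd.concat([in_alu, refined])
    assert sorted(survivors["pos"]) == [100, 600]


def test_duplicated_flank_removed_unique_flank_kept():
    rng = np.random.default_rng(2)
    core = "".join(rng.choice(list("ACGT"), 500))
    dup = core[180:280]               # site at pos 230 sits mid-duplication
    seqs = {"chr1": core + dup}
    calls = calls_df([
        ("chr1", 230, "A", "G", "P01", "RNA", "tumor", 0.30),
        ("chr1", 60, "A", "G", "P01", "RNA", "tumor", 0.30),
    ])
    refined = filter_non_alu(calls, seqs)
    assert list(refined["pos"]) == [60]


def test_flank_window_off_contig_retains_site():
    seqs = {"chr1": "".join(np.random.default_rng(3).choice(list("ACGT"),
                                                            200))}
    calls = calls_df([("chr1", 5, "A", "G", "P01", "RNA", "tumor", 0.30)])
    assert len(filter_non_alu(calls, seqs)) == 1


def test_reverse_complement_duplication_detected():
    from aiedit._util import revcomp
    rng = np.random.default_rng(4)
    core = "".join(rng.choice(list("ACGT"), 500))
    seqs = {"chr1": core + revcomp(core[180:280])}
    calls = calls_df([("chr1", 230, "A", "G", "P01", "RNA", "tumor", 0.30)])
    assert filter_non_alu(calls, seqs).empty


def test_mappability_bed_hook_replaces_kmer_check():
    lowmap = intervals(("chr1", 200, 260))
    calls = calls_df([
        ("chr1", 230, "A", "G", "P01", "RNA", "tumor", 0.30),
        ("chr1", 400, "A", "G", "P01", "RNA", "tumor", 0.30),
    ])
    refined = filter_non_alu(calls, sequences=None, mappability=lowmap)
    assert list(refined["pos"]) == [400]


# ---------------------------------------------------------------------------
# mismatch classification and consequences
# ---------------------------------------------------------------------------

def test_twelve_types_exhaustive_and_unique():
    seen_plus, seen_minus = set(), set()
    for ref, alt in product("ACGT", "ACGT"):
        if ref == alt:
            continue
        t_plus = classify_mismatch(ref, alt, "+")
        t_minus = classify_mismatch(ref, alt, "-")
        assert t_plus == f"{ref}-to-{alt}"
        assert t_minus == f"{complement(ref)}-to-{complement(alt)}"
        seen_plus.add(t_plus)
        seen_minus.add(t_minus)
    assert len(seen_plus) == 12 and len(seen_minus) == 12


def test_minus_strand_tc_collapses_to_a_to_g():
    assert classify_mismatch("T", "C", "-") == "A-to-G"
    assert classify_mismatch("A", "G", "+") == "A-to-G"


def test_classify_rejects_bad_input():
    with pytest.raises(ValueError):
        classify_mismatch("A", "A", "+")
    with pytest.raises(ValueError):
        classify_mismatch("A", "G", ".")


def _gene_with_cds(cds: str, strand: str = "+", pad: int = 30):
    """Embed a CDS (given on the transcript strand) in a synthetic contig."""
    from aiedit._util import revcomp
    rng = np.random.default_rng(9)
    left = "".join(rng.choice(list("ACGT"), pad))
    right = "".join(rng.choice(list("ACGT"), pad))
    genomic = cds if strand == "+" else revcomp(cds)
    seq = left + genomic + right
    gene = GeneModel("chr1", 0, len(seq), "G1", strand, pad, pad + len(cds))
    return gene, {"chr1": seq}


def test_recoding_at_cds_position_22_is_met8val():
    """An A>G at CDS position 22 edits codon 8 from ATG to GTG: p.M8V."""
    cds = "ATG" + "GCT" * 6 + "ATG" + "GCT" * 4   # codon 8 is ATG
    gene, seqs = _gene_with_cds(cds, "+")
    pos = gene.cds_start + 21 + 1                  # CDS position 22, 1-based
    cons = annotate_consequence("chr1", pos, "G", gene, seqs)
    assert cons.codon_index == 8
    assert (cons.ref_aa, cons.alt_aa) == ("M", "V")
    assert not cons.synonymous
    assert cons.hgvs_p == "p.M8V"


def test_recoding_on_minus_strand_gene():
    cds = "ATG" + "GCT" * 6 + "ATG" + "GCT" * 4
    gene, seqs = _gene_with_cds(cds, "-")
    # CDS position 22 on the transcript = genomic cds_end - 22 (0-based)
    pos0 = gene.cds_end - 22
    cons = annotate_consequence("chr1", pos0 + 1, "C", gene, seqs)
    assert cons.codon_index == 8
    assert cons.hgvs_p == "p.M8V"


def test_first_cds_base_is_codon_one():
    gene, seqs = _gene_with_cds("ATG" + "GCT" * 5, "+")
    cons = annotate_consequence("chr1", gene.cds_start + 1, "G", gene, seqs)
    assert cons.codon_index == 1
    assert cons.cds_pos == 1


def test_cds_position_1099_is_codon_367():
    cds = "ATG" + "GCT" * 400                      # 1203 bases
    gene, seqs = _gene_with_cds(cds, "+")
    pos = gene.cds_start + 1098 + 1
    cons = annotate_consequence("chr1", pos, "G", gene, seqs)
    assert cons.codon_index == 367


def test_synonymous_third_position_change():
    cds = "ATG" + "CCA" + "GCT" * 4                # CCA>CCG is still Pro
    gene, seqs = _gene_with_cds(cds, "+")
    cons = annotate_consequence("chr1", gene.cds_start + 6, "G", gene, seqs)
    assert cons.synonymous and cons.ref_aa == "P"


def test_utr_site_has_no_codon_fields():
    gene, seqs = _gene_with_cds("ATG" + "GCT" * 5, "+")
    cons = annotate_consequence("chr1", 5, "G", gene, seqs)  # in 5' pad
    assert cons.region == "UTR"
    assert cons.codon_index is None and cons.hgvs_p is None


# ---------------------------------------------------------------------------
# site assembly
# ---------------------------------------------------------------------------

def _assembly_inputs():
    gene, seqs = _gene_with_cds("ATG" + "GCT" * 6 + "ATG" + "GCT" * 4, "+")
    pos = gene.cds_start + 22
    calls = calls_df([
        ("chr1", pos, "A", "G", "P01", "RNA", "tumor", 0.3),
        ("chr1", pos, "A", "G", "P01", "RNA", "normal", 0.2),
        ("chr1", pos, "A", "G", "P02", "RNA", "tumor", 0.4),
    ])
    return gene, seqs, pos, calls


def test_recurrence_counted_per_patient_by_default():
    gene, seqs, pos, calls = _assembly_inputs()
    sites = assemble_editing_sites(calls, [gene], seqs, intervals(),
                                   intervals())
    assert len(sites) == 1
    assert sites.loc[0, "recurrence"] == 2          # P01 counts once
    assert sites.loc[0, "mismatch_type"] == "A-to-G"
    assert sites.loc[0, "hgvs_p"] == "p.M8V"


def test_recurrence_per_sample_mode():
    gene, seqs, pos, calls = _assembly_inputs()
    sites = assemble_editing_sites(calls, [gene], seqs, intervals(),
                                   intervals(), recurrence_unit="sample")
    assert sites.loc[0, "recurrence"] == 3


def test_db_and_conservation_joined():
    gene, seqs, pos, calls = _assembly_inputs()
    db = pd.DataFrame([("chr1", pos, "+")], columns=["chrom", "pos", "strand"])
    cons = pd.DataFrame([("chr1", pos, 1.7)],
                        columns=["chrom", "pos", "score"])
    sites = assemble_editing_sites(calls, [gene], seqs, intervals(),
                                   intervals(), conservation=cons,
                                   db_sites=db)
    assert bool(sites.loc[0, "db_known"])
    assert sites.loc[0, "conservation"] == pytest.approx(1.7)


# ---------------------------------------------------------------------------
# whole-cascade properties
# ---------------------------------------------------------------------------

def brute_force_cascade(rna_calls, dna_support, snps, repeats, alu, seqs,
                        k=50):
    """Independent set-algebra recomputation of the cascade survivors."""
    dna_keys = {(r.sample, r.chrom, r.pos, r.alt)
                for r in dna_support.itertuples()}
    known = {(r.chrom, r.pos, r.alt) for r in snps.itertuples()
             if float(r.maf) > 0.001}

    def in_iv(df, chrom, pos):
        return any(r.chrom == chrom and r.start <= pos < r.end
                   for r in df.itertuples())

    genome = seqs["chr1"]
    from aiedit._util import revcomp

    def unique_flank(pos):
        lo = pos - 1 - k // 2
        hi = lo + k
        if lo < 0 or hi > len(genome):
            return True
        kmer = genome[lo:hi]
        n = genome.count(kmer) + (0 if kmer == revcomp(kmer)
                                  else genome.count(revcomp(kmer)))
        return n <= 1

    survivors = []
    for r in rna_calls.itertuples():
        if (r.sample, r.chrom, r.pos, r.alt) in dna_keys:
            continue
        if (r.chrom, r.pos, r.alt) in known:
            continue
        if in_iv(repeats, r.chrom, r.pos):
            continue
        if not in_iv(alu, r.chrom, r.pos):
            if r.vaf < 0.10 or not unique_flank(r.pos):
                continue
        survivors.append((r.sample, r.tissue, r.chrom, r.pos, r.alt))
    return set(survivors)


def test_cascade_equals_brute_force_set_algebra(small_cohort):
    ref = small_cohort.reference
    rna = varcall.call_variants(
        small_cohort.counts.query("material == 'RNA'"),
        gene_intervals=ref.gene_intervals())
    assert len(rna) <= 500
    dna = dna_support_table(small_cohort.counts.query("material == 'DNA'"))
    result = run_cascade(rna, dna, ref.snps, ref.simple_repeats, ref.alu,
                         ref.sequences, ref.genes)
    got = set(zip(result.surviving_calls["sample"],
                  result.surviving_calls["tissue"],
                  result.surviving_calls["chrom"],
                  result.surviving_calls["pos"],
                  result.surviving_calls["alt"]))
    expected = brute_force_cascade(rna, dna, ref.snps, ref.simple_repeats,
                                   ref.alu, ref.sequences)
    assert got == expected


def test_set_subtraction_stages_commute(small_cohort):
    ref = small_cohort.reference
    rna = varcall.call_variants(
        small_cohort.counts.query("material == 'RNA'"),
        gene_intervals=ref.gene_intervals())
    dna = dna_support_table(small_cohort.counts.query("material == 'DNA'"))

    def key_set(df):
        return set(zip(df["sample"], df["tissue"], df["pos"], df["alt"]))

    a = filter_simple_repeats(
        filter_known_snps(subtract_dna_variants(rna, dna), ref.snps),
        ref.simple_repeats)
    b = subtract_dna_variants(
        filter_known_snps(filter_simple_repeats(rna, ref.simple_repeats),
                          ref.snps), dna)
    assert key_set(a) == key_set(b)


def test_zero_leakage_on_error_free_cohort(clean_cohort):
    result = discover_editing_sites(clean_cohort)
    bench = benchmark_against_truth(result, clean_cohort)
    assert bench.snp_leakage == 0
    assert bench.somatic_leakage == 0
    assert bench.precision == 1.0


def test_strand_involution_preserves_mismatch_spectrum(clean_cohort):
    """Complementing the reference, flipping gene strands and swapping read
    strands leaves the strand-collapsed mismatch distribution unchanged."""
    from aiedit._util import revcomp
    result = discover_editing_sites(clean_cohort)
    original = result.sites["mismatch_type"].value_counts().to_dict()
    flipped = [classify_mismatch(complement(r.ref), complement(r.alt),
                                 "-" if r.gene_strand == "+" else "+")
               for r in result.sites.itertuples()]
    assert pd.Series(flipped).value_counts().to_dict() == original
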