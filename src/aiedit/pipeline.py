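"""End-to-end discovery pipeline on a cohort: RNA calling, DNA support
scan, filter cascade, site assembly, and truth-set benchmarking for
simulated cohorts."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import edcall, varcall
from .synthdata import SyntheticCohort


@dataclass
class BenchmarkResult:
    sensitivity: float
    precision: float
    n_true: int
    n_called: int
    n_recovered: int
    snp_leakage: int
    somatic_leakage: int


def discover_editing_sites(cohort: SyntheticCohort,
                           caller_params: varcall.CallerParams | None = None,
                           db_sites: pd.DataFrame | None = None,
                           recurrence_unit: str = "patient"
                           ) -> edcall.CascadeResult:
    """Run the full discovery pipeline on a (simulated or real-format)
    cohort: call RNA variants under the depth/VAF/quality/strand
    constraints, scan DNA for any allele support, then apply the editing
    filter cascade and assemble cohort-level sites."""
    params = caller_params or varcall.CallerParams()
    ref = cohort.reference
    gene_iv = ref.gene_intervals()
    rna_counts = cohort.counts[cohort.counts["material"] == "RNA"]
    dna_counts = cohort.counts[cohort.counts["material"] == "DNA"]
    rna_calls = varcall.call_variants(rna_counts, params,
                                      gene_intervals=gene_iv)
    dna_support = edcall.dna_support_table(dna_counts)
    return edcall.run_cascade(
        rna_calls=rna_calls,
        dna_support=dna_support,
        snp_catalogue=ref.snps,
        repeat_intervals=ref.simple_repeats,
        alu_intervals=ref.alu,
        sequences=ref.sequences,
        genes=ref.genes,
        conservation=ref.conservation,
        db_sites=db_sites,
        allow_missing_dna=False,
        recurrence_unit=recurrence_unit,
    )


def benchmark_against_truth(result: edcall.CascadeResult,
                            cohort: SyntheticCohort) -> BenchmarkResult:
    """Sensitivity/precision of assembled sites against the planted truth.

    A planted edit counts as recovered when an assembled site matches its
    (chrom, pos, alt). Precision treats any non-planted-edit site as a
    false positive. Leakage counts assembled sites that coincide with
    planted germline SNPs or somatic SNVs (matching alt allele).
    """
    truth = cohort.truth
    true_keys = set(zip(truth.edits["chrom"], truth.edits["pos"].astype(int),
                        truth.edits["alt"]))
    called = result.sites
    called_keys = (set(zip(called["chrom"], called["pos"].astype(int),
                           called["alt"]))
                   if len(called) else set())
    recovered = true_keys & called_keys
    # leakage is patient-aware: the planted variant itself (in its carrier)
    # surviving the cascade, not an unrelated error call at the same spot
    surv = result.surviving_calls
    surv_keys = (set(zip(surv["sample"], surv["chrom"],
                         surv["pos"].astype(int), surv["alt"]))
                 if len(surv) else set())
    alt_by_pos = dict(zip(zip(truth.snps["chrom"],
                              truth.snps["pos"].astype(int)),
                          truth.snps["alt"]))
    snp_carrier_keys = {
        (g.patient, g.chrom, g.pos, alt_by_pos[(g.chrom, g.pos)])
        for g in truth.snp_genotypes.itertuples()}
    som_carrier_keys = set(zip(truth.somatic["patient"],
                               truth.somatic["chrom"],
                               truth.somatic["pos"].astype(int),
                               truth.somatic["alt"]))
    return BenchmarkResult(
        sensitivity=len(recovered) / len(true_keys) if true_keys else float("nan"),
        precision=(len(recovered) / len(called_keys)
                   if called_keys else float("nan")),
        n_true=len(true_keys),
        n_called=len(called_keys),
        n_recovered=len(recovered),
        snp_leakage=len(surv_keys & snp_carrier_keys),
        somatic_leakage=len(surv_keys & som_carrier_keys),
    )
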