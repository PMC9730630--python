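"""Reference benchmarks: worked-example arithmetic and simulation studies.

These functions reproduce, from the package's own operations, the two kinds
of headline numbers an editing study prints: (a) summary arithmetic over
published site counts (singleton percentages, database and Alu fractions,
over-edited patient fractions, the p.M8V recoding annotation), and (b)
calibration studies on synthetic cohorts (planted-site recovery, null
behavior of the editing-expression correlation, Sanger round-trip error).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import edassoc, edcall, edprofile, sangerq
from .pipeline import benchmark_against_truth, discover_editing_sites
from .synthdata import (CohortConfig, GeneModel, generate_reference,
                        simulate_chromatogram, simulate_cohort)
from ._util import pct


def discovery_summary_arithmetic() -> dict:
    """Summaries of the discovery-cohort site counts (409 putative sites,
    373 singletons, 63 known in editing databases; 36 recurrent sites of
    which 24 known and — among the 29 A-to-G ones — 17 in Alu; 15 patients
    of which 10 over-edited; 25 validated sites, 14 nonsynonymous + 11
    synonymous), recomputed through the package summarizers."""
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(409) + 1,
        "mismatch_type": "A-to-G",
        "is_alu": False,
        "db_known": [True] * 63 + [False] * 346,
        "recurrence": [2] * 24 + [1] * 39 + [2] * 12 + [1] * 334,
    })
    rec = edprofile.recurrence_summary(sites)
    spectrum = edprofile.spectrum_fractions(sites)
    recurrent_ag = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(29) + 1,
        "mismatch_type": "A-to-G",
        "is_alu": [True] * 17 + [False] * 12,
        "db_known": False, "recurrence": 2,
    })
    alu = edprofile.spectrum_fractions(recurrent_ag)
    over = [edprofile.PatientEditingSummary(f"P{i + 1:02d}",
                                            n_over=3 if i < 10 else 1,
                                            n_under=1 if i < 10 else 3)
            for i in range(15)]
    n_dom = sum(1 for s in over if s.n_over > s.n_under)
    n_nonsyn, n_syn = 14, 11
    return {
        "n_total_sites": rec["n_total"],
        "singleton_pct": rec["singleton_pct"],
        "n_recurrent": rec["n_recurrent"],
        "db_pct_all": spectrum["all"]["db_pct"],
        "db_pct_recurrent": spectrum["recurrent"]["db_pct"],
        "alu_pct_recurrent_ag": alu["recurrent"]["alu_pct"],
        "overedited_patient_pct": pct(n_dom, len(over)),
        "n_validated_sites": n_nonsyn + n_syn,
    }


def recoding_annotation_example() -> dict:
    """Annotate an A>G edit at CDS position 22 of a transcript whose eighth
    codon is ATG: the editing event that produces the Met8Val substitution."""
    cds = "ATG" + "GCT" * 6 + "ATG" + "GCT" * 20
    pad = 30
    seq = "C" * pad + cds + "C" * pad
    gene = GeneModel("chr1", 0, len(seq), "KPC1-like", "+", pad,
                     pad + len(cds))
    cons = edcall.annotate_consequence("chr1", pad + 22, "G", gene,
                                       {"chr1": seq})
    return {
        "cds_position": 22,
        "codon_index": cons.codon_index,
        "ref_aa": cons.ref_aa,
        "alt_aa": cons.alt_aa,
        "nonsynonymous": not cons.synonymous,
        "hgvs_p": cons.hgvs_p,
    }


def pipeline_recovery(seed: int = 1) -> dict:
    """Run the whole discovery pipeline on the default synthetic cohort and
    benchmark the assembled sites against the planted truth."""
    cohort = simulate_cohort(CohortConfig(seed=seed))
    result = discover_editing_sites(cohort)
    bench = benchmark_against_truth(result, cohort)
    return {
        "sensitivity": bench.sensitivity,
        "precision": bench.precision,
        "n_true_edits": bench.n_true,
        "n_called_sites": bench.n_called,
        "snp_leakage": bench.snp_leakage,
        "somatic_leakage": bench.somatic_leakage,
    }


def _panel_config(seed: int, adar_coupling: float,
                  n_patients: int = 15) -> CohortConfig:
    """A validated-panel-style cohort: a fixed set of 25 sites edited in
    every patient, no confounding variant classes."""
    return CohortConfig(
        n_patients=n_patients, genome_length=40_000, n_genes=15,
        n_edit_sites=25, n_snps=0, n_somatic=0, n_background=0,
        depth_mean_rna=50, depth_mean_dna=50, seq_error_rate=1e-3,
        adar_coupling=adar_coupling,
        recurrence_profile={n_patients: 1.0}, seed=seed,
    )


def _cohort_burden_correlation(cohort) -> edassoc.AssociationResult:
    truth = cohort.truth
    matrix = edprofile.level_matrix(
        cohort.counts, truth.edits[["chrom", "pos", "ref", "alt"]])
    summaries, _ = edprofile.patient_overediting(matrix)
    burden = pd.Series({s.patient: s.over_fraction
                        for s in summaries}).dropna()
    return edassoc.burden_expression_correlation(
        burden, cohort.expression, gene="ADAR1-p110", method="approx")


def correlation_calibration(n_reps: int = 200, seed: int = 0,
                            adar_coupling: float = 0.0) -> dict:
    """Distribution of the editing-burden vs ADAR1-p110 Spearman test over
    replicate cohorts at a given coupling.

    With ``adar_coupling=0`` this is a null calibration: the positive-rho
    fraction should sit at chance and the fraction of p < 0.05 at the
    nominal type-I error. The site panel and annotations are generated once
    and held fixed across replicates; expression, editing levels and read
    counts are redrawn each time.
    """
    skeleton = _panel_config(seed=int(seed) % (2 ** 31 - 1) or 1,
                             adar_coupling=adar_coupling)
    reference = generate_reference(skeleton)
    rhos, pvals = [], []
    for rep in range(n_reps):
        cfg = _panel_config(seed=(skeleton.seed + 7919 * (rep + 1)) % (2 ** 31),
                            adar_coupling=adar_coupling)
        cohort = simulate_cohort(cfg, reference=reference)
        res = _cohort_burden_correlation(cohort)
        rhos.append(res.estimate)
        pvals.append(res.p_value)
    rhos = np.array(rhos)
    pvals = np.array(pvals)
    return {
        "n_reps": n_reps,
        "mean_rho": float(rhos.mean()),
        "positive_rho_fraction": float((rhos > 0).mean()),
        "type_i_error_at_0.05": float((pvals < 0.05).mean()),
    }


def sanger_round_trip(levels: tuple[float, ...] = (0.10, 0.30, 0.50),
                      n_seeds: int = 20, noise_sd: float = 5.0,
                      seed: int = 0) -> dict:
    """Mean absolute error (percentage points) of trace-based editing
    estimates across simulated chromatograms at known levels."""
    context = "CCTCTAGCTCC"
    errors = []
    per_level = {}
    for level in levels:
        errs = []
        for i in range(n_seeds):
            trace = simulate_chromatogram(
                level, context, noise_sd=noise_sd,
                seed=(seed * 1000 + int(level * 100) * 37 + i) % (2 ** 31))
            est = sangerq.estimate_editing(trace, len(context) // 2)
            errs.append(abs(est.percent - 100.0 * level))
        per_level[level] = float(np.mean(errs))
        errors.extend(errs)
    return {"mae_pct": float(np.mean(errors)), "per_level": per_level}
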