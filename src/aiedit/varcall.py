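"""Threshold variant calling from stranded base-count tables.

A transparent re-implementation of the constrained calling step used for
RNA-editing discovery: a candidate variant is emitted when the site reaches
at least 8x depth, the alternate allele reaches a variation frequency (VAF)
of at least 5%, the alternate-supporting bases average Phred quality >= 20,
and the read-strand distribution of ref vs alt shows no significant bias
(two-sided Fisher exact test on the 2x2 strand table). All four thresholds
are parameters; the defaults are the published ones. Calling operates on
DNA and RNA tables alike and is restricted to annotated gene territory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ._util import BASES

logger = logging.getLogger(__name__)

FWD_COLS = {b: f"{b}_fwd" for b in BASES}
REV_COLS = {b: f"{b}_rev" for b in BASES}
QUAL_COLS = {b: f"meanQ_{b}" for b in BASES}


@dataclass(frozen=True)
class CallerParams:
    """Calling thresholds. Comparisons are inclusive: depth 8 and VAF 0.05
    pass at the defaults."""

    min_depth: int = 8
    min_vaf: float = 0.05
    min_baseq: float = 20.0
    strand_bias_alpha: float = 0.05
    min_alt_for_bias_test: int = 2   # below this the Fisher test is skipped


def strand_bias_test(row: pd.Series | dict, alt: str) -> float:
    """Two-sided Fisher exact p-value of the {ref, alt} x {fwd, rev} table.

    Returns 1.0 when the alternate allele is absent (nothing to test).
    """
    ref = row["ref"]
    table = np.array([
        [row[FWD_COLS[ref]], row[REV_COLS[ref]]],
        [row[FWD_COLS[alt]], row[REV_COLS[alt]]],
    ], dtype=np.int64)
    if table.sum() < 1 or table[0].sum() + table[1].sum() < 1:
        raise ValueError("ref+alt reads must be >= 1 for the strand test")
    if table[1].sum() == 0:
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def _site_depth(row) -> int:
    return int(sum(row[FWD_COLS[b]] + row[REV_COLS[b]] for b in BASES))


def restrict_to_genes(counts: pd.DataFrame,
                      gene_intervals: pd.DataFrame) -> pd.DataFrame:
    """Keep count rows whose 1-based position falls inside a gene interval
    (0-based half-open)."""
    if gene_intervals.empty:
        return counts.iloc[0:0]
    keep = np.zeros(len(counts), dtype=bool)
    pos0 = counts["pos"].to_numpy() - 1
    for _, g in gene_intervals.iterrows():
        keep |= ((counts["chrom"].to_numpy() == g["chrom"])
                 & (pos0 >= g["start"]) & (pos0 < g["end"]))
    return counts.loc[keep]


def call_variants(counts: pd.DataFrame,
                  params: CallerParams = CallerParams(),
                  gene_intervals: pd.DataFrame | None = None,
                  keep_filtered: bool = False) -> pd.DataFrame:
    """Call candidate variants from a base-count table.

    One output row per (site, sample, material, tissue, alt allele) whose
    alternate allele passes — or, with ``keep_filtered``, fails with a
    recorded reason — the depth / VAF / base-quality / strand-bias
    constraints. VAF is alt/(ref+alt); alleles other than the tested alt
    are ignored in the denominator, and a site can emit one call per
    non-reference allele.
    """
    if gene_intervals is not None:
        counts = restrict_to_genes(counts, gene_intervals)
    records = []
    for _, row in counts.iterrows():
        ref = row["ref"]
        if ref not in BASES:
            logger.warning("skipping %s:%s: unknown reference base %r",
                           row["chrom"], row["pos"], ref)
            continue
        per_base = {b: int(row[FWD_COLS[b]]) + int(row[REV_COLS[b]])
                    for b in BASES}
        if any(v < 0 for v in per_base.values()):
            raise ValueError(
                f"negative base count at {row['chrom']}:{row['pos']}")
        depth = sum(per_base.values())
        for alt in BASES:
            if alt == ref or per_base[alt] == 0:
                continue
            denom = per_base[ref] + per_base[alt]
            vafv = per_base[alt] / denom if denom else 0.0
            status = "PASS"
            if depth < params.min_depth:
                status = "low_depth"
            elif vafv < params.min_vaf:
                status = "low_vaf"
            elif float(row[QUAL_COLS[alt]]) < params.min_baseq:
                status = "low_baseq"
            sb_p = 1.0
            if per_base[alt] >= params.min_alt_for_bias_test and denom >= 1:
                sb_p = strand_bias_test(row, alt)
                if status == "PASS" and sb_p < params.strand_bias_alpha:
                    status = "strand_bias"
            if status != "PASS" and not keep_filtered:
                continue
            records.append((row["chrom"], int(row["pos"]), ref, alt,
                            row["sample"], row["material"], row["tissue"],
                            vafv, depth, per_base[alt], sb_p,
                            float(row[QUAL_COLS[alt]]), status))
    return pd.DataFrame(records, columns=[
        "chrom", "pos", "ref", "alt", "sample", "material", "tissue",
        "vaf", "depth", "alt_count", "strand_bias_p", "mean_alt_quality",
        "filter_status",
    ])
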