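"""Cohort-level descriptive statistics of an editing-site set.

Covers the discovery-style summaries: editing levels per site/sample,
singleton vs recurrent fractions, mismatch-type spectrum and Alu /
known-database fractions, per-patient over- vs under-editing relative to
matched normal tissue (a site is over-edited in a patient when its tumor
editing level exceeds the normal level by more than 10 percentage points),
and the +/-10 nt neighbor-preference matrix around A-to-I sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import BASES, pct, revcomp

logger = logging.getLogger(__name__)


def editing_level(row, alt: str, min_depth: int = 1) -> float:
    """Editing level = alt/(ref+alt) read counts; NaN below ``min_depth``
    informative (ref+alt) reads."""
    ref = row["ref"]
    n_ref = int(row[f"{ref}_fwd"]) + int(row[f"{ref}_rev"])
    n_alt = int(row[f"{alt}_fwd"]) + int(row[f"{alt}_rev"])
    denom = n_ref + n_alt
    if denom < min_depth or denom == 0:
        return float("nan")
    return n_alt / denom


def level_matrix(counts: pd.DataFrame, sites: pd.DataFrame,
                 min_depth: int = 8) -> pd.DataFrame:
    """Editing levels of given (chrom,pos,ref,alt) sites across all RNA
    samples: long table (chrom, pos, patient, tissue, level). Cells with
    fewer than ``min_depth`` informative reads are absent."""
    rna = counts[counts["material"] == "RNA"]
    site_keys = set(zip(sites["chrom"], sites["pos"].astype(int)))
    alt_map = {(c, int(p)): a
               for c, p, a in zip(sites["chrom"], sites["pos"], sites["alt"])}
    rows = []
    for _, row in rna.iterrows():
        key = (row["chrom"], int(row["pos"]))
        if key not in site_keys:
            continue
        lvl = editing_level(row, alt_map[key], min_depth=min_depth)
        if np.isnan(lvl):
            continue
        rows.append((key[0], key[1], row["sample"], row["tissue"], lvl))
    return pd.DataFrame(rows, columns=["chrom", "pos", "patient", "tissue",
                                       "level"])


def recurrence_summary(sites: pd.DataFrame) -> dict:
    """Singleton/recurrent breakdown of an editing-site table (or any table
    with a ``recurrence`` column)."""
    n_total = len(sites)
    n_singleton = int((sites["recurrence"] == 1).sum())
    return {
        "n_total": n_total,
        "n_singleton": n_singleton,
        "n_recurrent": n_total - n_singleton,
        "singleton_pct": pct(n_singleton, n_total) if n_total else float("nan"),
    }


def spectrum_fractions(sites: pd.DataFrame) -> dict:
    """Mismatch-type spectrum plus Alu and known-database fractions, each
    reported over all sites and over the recurrent (>= 2 patients) subset,
    with raw numerators/denominators kept alongside the percentages."""
    def block(subset: pd.DataFrame) -> dict:
        n = len(subset)
        by_type = subset["mismatch_type"].value_counts().to_dict()
        out = {
            "n": n,
            "mismatch_counts": by_type,
            "mismatch_pct": {t: pct(c, n) for t, c in by_type.items()} if n else {},
        }
        for label, col in (("alu", "is_alu"), ("db", "db_known")):
            k = int(subset[col].sum()) if n else 0
            out[f"n_{label}"] = k
            out[f"{label}_pct"] = pct(k, n) if n else float("nan")
        return out

    recurrent = sites[sites["recurrence"] >= 2]
    return {"all": block(sites), "recurrent": block(recurrent)}


@dataclass
class PatientEditingSummary:
    patient: str
    n_over: int
    n_under: int

    @property
    def over_fraction(self) -> float:
        denom = self.n_over + self.n_under
        return self.n_over / denom if denom else float("nan")


def patient_overediting(matrix: pd.DataFrame, delta: float = 0.10
                        ) -> tuple[list[PatientEditingSummary], dict]:
    """Per-patient over-/under-editing from a long level table.

    ``matrix`` columns: chrom, pos, patient, tissue, level. For each
    patient, a site counts as over-edited when tumor - normal > ``delta``
    (strict) and under-edited when normal - tumor > ``delta``; site/patient
    pairs missing either tissue are excluded. The cohort summary reports
    the fraction of evaluable patients with more over- than under-edited
    sites.
    """
    wide = matrix.pivot_table(index=["chrom", "pos", "patient"],
                              columns="tissue", values="level",
                              aggfunc="first").reset_index()
    summaries = []
    for patient, grp in wide.groupby("patient", sort=True):
        if "tumor" not in grp.columns or "normal" not in grp.columns:
            paired = grp.iloc[0:0]
        else:
            paired = grp.dropna(subset=["tumor", "normal"])
        if paired.empty:
            logger.info("patient %s has no site with both tissues; excluded",
                        patient)
            continue
        diff = paired["tumor"] - paired["normal"]
        summaries.append(PatientEditingSummary(
            patient=str(patient),
            n_over=int((diff > delta).sum()),
            n_under=int((-diff > delta).sum()),
        ))
    n_eval = len(summaries)
    n_over_dom = sum(1 for s in summaries if s.n_over > s.n_under)
    cohort = {
        "n_patients_evaluated": n_eval,
        "n_over_dominant": n_over_dom,
        "over_dominant_pct": pct(n_over_dom, n_eval) if n_eval else float("nan"),
    }
    return summaries, cohort


def motif_profile(sites: pd.DataFrame, sequences: dict[str, str],
                  window: int = 10) -> pd.DataFrame:
    """Base-frequency matrix at positions -window..+window around A-to-I
    sites, on the edited (transcribed) strand.

    ``sites`` columns: chrom, pos, gene_strand. Minus-strand contexts are
    reverse-complemented before counting so the center is always A. Sites
    whose window runs off the contig are dropped with a warning. Each row
    of the result sums to 1.
    """
    counts = np.zeros((2 * window + 1, 4))
    used = 0
    for _, row in sites.iterrows():
        seq = sequences[row["chrom"]]
        pos0 = int(row["pos"]) - 1
        lo, hi = pos0 - window, pos0 + window + 1
        if lo < 0 or hi > len(seq):
            logger.warning("site %s:%s too close to contig end; dropped",
                           row["chrom"], row["pos"])
            continue
        ctx = seq[lo:hi]
        if row["gene_strand"] == "-":
            ctx = revcomp(ctx)
        if ctx[window] != "A":
            raise ValueError(
                f"site {row['chrom']}:{row['pos']} is not an A on the "
                "transcribed strand; strand-collapse it first")
        for i, b in enumerate(ctx):
            counts[i, BASES.index(b)] += 1
        used += 1
    if used == 0:
        raise ValueError("no site with a complete context window")
    freqs = counts / used
    return pd.DataFrame(freqs, columns=list(BASES),
                        index=pd.Index(range(-window, window + 1),
                                       name="offset"))
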