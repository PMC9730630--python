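"""Association statistics linking editing to ADAR expression and tissue.

Spearman rank correlations (exact permutation p-value for small n, the
usual t approximation otherwise) between per-patient editing burden — or
per-site editing levels — and expression of an ADAR isoform; paired t
tests of tumor vs matched normal editing levels; and simple expression
fold changes (tumor/normal within a gene, or gene A vs gene B).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AssociationResult:
    statistic: str
    estimate: float
    p_value: float
    n: int


EXACT_PERM_MAX_N = 9   # 9! = 362,880 permutations; exact above this is wasteful


def spearman(x, y, method: str = "auto") -> AssociationResult:
    """Spearman rho with mid-ranked ties.

    ``method``: "exact" enumerates all permutations of one vector (two-sided
    p = fraction of permutations with |rho| >= |observed|), "approx" uses
    the t approximation, "auto" picks exact for n <= 9.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors required")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a correlation")
    if method == "auto":
        method = "exact" if n <= EXACT_PERM_MAX_N else "approx"
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    denom = rx.std() * ry.std()
    if denom == 0:
        return AssociationResult("spearman_rho", float("nan"), float("nan"), n)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "approx":
        p = float(stats.spearmanr(x, y).pvalue)
    elif method == "exact":
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        scale = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        perms = np.array(list(permutations(range(n))))
        rhos = (rx_c[perms] @ ry_c) / scale
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        raise ValueError(f"unknown method {method!r}")
    return AssociationResult("spearman_rho", rho, p, n)


def _expression_vector(expression: pd.DataFrame, gene: str, tissue: str,
                       patients) -> np.ndarray:
    sub = expression.query("gene == @gene and tissue == @tissue")
    by_patient = sub.set_index("patient")["fpkm"]
    missing = [p for p in patients if p not in by_patient.index]
    if missing:
        raise KeyError(f"no {gene} {tissue} expression for patients {missing}")
    return by_patient.loc[list(patients)].to_numpy(dtype=float)


def burden_expression_correlation(over_fraction: pd.Series,
                                  expression: pd.DataFrame,
                                  gene: str = "ADAR1-p110",
                                  tissue: str = "tumor",
                                  method: str = "auto") -> AssociationResult:
    """Correlate each patient's over-editing burden (e.g. percentage of
    over-edited sites) with tumor expression of an ADAR isoform.

    ``over_fraction`` is indexed by patient id; patients with NaN burden
    are dropped.
    """
    burden = over_fraction.dropna()
    expr = _expression_vector(expression, gene, tissue, burden.index)
    return spearman(burden.to_numpy(dtype=float), expr, method=method)


def site_level_correlation(levels: pd.Series, expression: pd.DataFrame,
                           gene: str = "ADAR1-p110", tissue: str = "tumor",
                           method: str = "auto") -> AssociationResult:
    """Correlate per-patient editing levels at one site with expression of
    an ADAR isoform (levels indexed by patient id)."""
    levels = levels.dropna()
    expr = _expression_vector(expression, gene, tissue, levels.index)
    return spearman(levels.to_numpy(dtype=float), expr, method=method)


def paired_tissue_test(levels_tumor, levels_normal,
                       log_transform: bool = False,
                       log_offset: float = 1e-3) -> AssociationResult:
    """Two-sided paired Student's t test of tumor vs matched normal values.

    Degenerate cases are guarded: identical vectors give t=0, p=1; a
    non-zero constant shift (zero-variance differences) gives p=0.
    """
    t_v = np.asarray(levels_tumor, dtype=float)
    n_v = np.asarray(levels_normal, dtype=float)
    if len(t_v) != len(n_v):
        raise ValueError("paired vectors required")
    if len(t_v) < 2:
        raise ValueError("need n >= 2 pairs")
    if log_transform:
        t_v = np.log(t_v + log_offset)
        n_v = np.log(n_v + log_offset)
    diff = t_v - n_v
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return AssociationResult("paired_t", 0.0, 1.0, len(diff))
        sign = float(np.sign(diff.mean()))
        return AssociationResult("paired_t", sign * float("inf"), 0.0,
                                 len(diff))
    res = stats.ttest_rel(t_v, n_v)
    return AssociationResult("paired_t", float(res.statistic),
                             float(res.pvalue), len(diff))


def expression_fold_change(expression: pd.DataFrame, gene: str,
                           tissue_pair: tuple[str, str] = ("tumor", "normal"),
                           other_gene: str | None = None) -> float:
    """Mean expression ratio.

    Default: mean(tumor)/mean(normal) within ``gene``. With ``other_gene``,
    the cross-gene ratio mean(gene)/mean(other_gene) within the first
    tissue of the pair.
    """
    hi, lo = tissue_pair
    a = expression.query("gene == @gene and tissue == @hi")["fpkm"]
    if other_gene is None:
        b = expression.query("gene == @gene and tissue == @lo")["fpkm"]
    else:
        b = expression.query("gene == @other_gene and tissue == @hi")["fpkm"]
    if a.empty or b.empty or b.mean() == 0:
        raise ValueError("fold change undefined for empty or zero groups")
    return float(a.mean() / b.mean())
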