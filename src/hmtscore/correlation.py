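"""Copy-number dosage / expression correlation.

For each gene the discrete GISTIC call is correlated with the expression
z-score over complete-case sample pairs, by three methods: Spearman rank
correlation (average ranks for the heavy ties a five-category call
produces), Kendall tau-b (tie-corrected), and Pearson.  P-values follow
the conventional approximations: a t distribution with n-2 degrees of
freedom for Spearman and Pearson, the tie-corrected normal approximation
for Kendall.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    gene: str
    n_pairs: int
    r_spearman: float
    p_spearman: float
    r_kendall: float
    p_kendall: float
    r_pearson: float
    p_pearson: float


def spearman_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Spearman coefficient via the t approximation.

    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom.
    """
    if n < 3:
        return np.nan
    r = float(r)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def dosage_correlation(cohort: Cohort, gene: str) -> CorrelationResult:
    """Spearman/Kendall/Pearson correlation between calls and expression."""
    if gene not in cohort.cn.index:
        raise KeyError(f"gene {gene!r} not in copy-number matrix")
    if gene not in cohort.expr.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    shared = [s for s in cohort.cn.columns if s in set(cohort.expr.columns)]
    x = cohort.cn.loc[gene, shared].to_numpy(dtype=float)
    y = cohort.expr.loc[gene, shared].to_numpy(dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"gene {gene!r}: only {n} complete pairs (need >= 3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("gene %s: zero variance; correlation undefined", gene)
        return CorrelationResult(gene, n, *(np.nan,) * 6)
    # Spearman p via the t approximation to match spearman_p_from_r exactly.
    rs = stats.spearmanr(x, y).statistic
    ps = spearman_p_from_r(rs, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns about ties w/ exact method
        kt = stats.kendalltau(x, y, variant="b", method="asymptotic")
    pr = stats.pearsonr(x, y)
    return CorrelationResult(
        gene, n,
        float(rs), float(ps),
        float(kt.statistic), float(kt.pvalue),
        float(pr.statistic), float(pr.pvalue),
    )


def dosage_correlations(cohort: Cohort, genes: Sequence[str]) -> pd.DataFrame:
    """Per-gene correlation table, indexed by gene."""
    rows = [dosage_correlation(cohort, g).__dict__ for g in genes]
    return pd.DataFrame(rows).set_index("gene")


def screen_high_correlation(
    results: pd.DataFrame, r_thresh: float = 0.5, p_thresh: float = 0.001
) -> list[str]:
    """Genes with Spearman r strictly above ``r_thresh`` and p strictly
    below ``p_thresh`` (the dosage-correlation criterion)."""
    sel = (results["r_spearman"] > r_thresh) & (results["p_spearman"] < p_thresh)
    return sorted(results.index[sel.fillna(False)])
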