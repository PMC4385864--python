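"""Alteration landscape: per-gene GISTIC-category and mutation frequencies,
threshold selection of the most-altered genes, and multi-locus
co-amplification breakdowns.

Frequencies use per-gene evaluable denominators (samples with a non-missing
call for that gene; samples in the universe for mutation frequency).  A
sample with several mutations in a gene counts once toward the mutation
frequency.  Percentages are kept unrounded internally; rounding to two
decimals happens only at reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, GISTIC_CALLS

logger = logging.getLogger(__name__)

#: Category -> frequency column, in the reporting order.
CATEGORY_COLUMNS = {
    2: "f_amp",
    1: "f_gain",
    0: "f_diploid",
    -1: "f_hetloss",
    -2: "f_homdel",
}

#: Subtypes entering the per-subtype breakdown; normal-like is excluded
#: because of its very small group size.
SUBTYPE_STRATA = ("LuminalA", "LuminalB", "HER2", "Basal")


def _gene_frequencies(calls: pd.Series, mut_samples: set[str], universe_n: int) -> dict:
    evaluable = calls.dropna()
    row: dict = {"n_evaluable_cn": int(len(evaluable)), "n_evaluable_mut": universe_n}
    if len(evaluable) == 0:
        logger.warning("no evaluable copy-number calls for gene %s", calls.name)
        for col in CATEGORY_COLUMNS.values():
            row[col] = np.nan
    else:
        counts = evaluable.value_counts()
        for call, col in CATEGORY_COLUMNS.items():
            row[col] = 100.0 * counts.get(call, 0) / len(evaluable)
    row["f_mut"] = (
        100.0 * len(mut_samples) / universe_n if universe_n else np.nan
    )
    return row


def alteration_frequencies(
    cohort: Cohort, genes: Sequence[str], by_subtype: bool = False
) -> pd.DataFrame:
    """Frequencies of each copy-number category and of mutation, per gene.

    Returns a DataFrame with one row per (gene, stratum); the overall
    stratum is labelled ``"all"``.  When ``by_subtype`` is set, rows for
    the four major subtypes are appended (normal-like excluded).
    """
    missing = [g for g in genes if g not in cohort.cn.index]
    if missing:
        raise KeyError(f"gene(s) absent from copy-number matrix: {missing}")

    strata: list[tuple[str, list[str]]] = [("all", list(cohort.samples))]
    if by_subtype:
        subtype = cohort.clinical["subtype"]
        for st in SUBTYPE_STRATA:
            strata.append((st, subtype.index[subtype == st].tolist()))

    mut = cohort.mutations
    rows = []
    for gene in genes:
        mutated = set(mut.loc[mut["gene"] == gene, "sample_id"])
        for label, samples in strata:
            calls = cohort.cn.loc[gene, [s for s in samples if s in cohort.cn.columns]]
            row = _gene_frequencies(
                calls.rename(gene), mutated & set(samples), len(samples)
            )
            rows.append({"gene": gene, "subtype": label, **row})
    return pd.DataFrame(rows).set_index(["gene", "subtype"])


def select_top_altered(
    summaries: pd.DataFrame,
    amp_thresh: float = 5.0,
    homdel_thresh: float = 2.0,
    mut_thresh: float = 2.0,
) -> pd.DataFrame:
    """Genes whose alteration frequency exceeds any of the three thresholds.

    ``summaries`` is gene-indexed (or (gene, "all")-indexed) with columns
    ``f_amp, f_homdel, f_mut`` in percent.  Selection uses strict
    inequalities; each selected gene is annotated with the rule(s) that
    fired (``amp``, ``homdel``, ``mut``).  Output is sorted by gene so the
    result is invariant to input order.
    """
    df = summaries
    if isinstance(df.index, pd.MultiIndex):
        df = df.xs("all", level="subtype")
    rows = []
    for gene, row in df.iterrows():
        reasons = []
        if row["f_amp"] > amp_thresh:
            reasons.append("amp")
        if row["f_homdel"] > homdel_thresh:
            reasons.append("homdel")
        if row["f_mut"] > mut_thresh:
            reasons.append("mut")
        if reasons:
            rows.append({"gene": gene, "reasons": ",".join(reasons)})
    out = pd.DataFrame(rows, columns=["gene", "reasons"])
    return out.sort_values("gene").reset_index(drop=True)


@dataclass
class ConcurrencyBreakdown:
    """Co-amplification structure over a set of loci.

    A sample is amplified at a locus iff its call is +2.  ``exclusive``
    counts samples amplified at exactly that one locus; ``pairwise`` counts
    samples amplified at both loci of each pair (regardless of others).
    """

    loci: list[str]
    n_any_amplified: int
    n_all_amplified: int
    exclusive: dict[str, int]
    pairwise: dict[tuple[str, str], int]

    def as_dict(self) -> dict:
        return {
            "loci": self.loci,
            "n_any_amplified": self.n_any_amplified,
            "n_all_amplified": self.n_all_amplified,
            "exclusive": dict(self.exclusive),
            "pairwise": {f"{a}|{b}": v for (a, b), v in self.pairwise.items()},
        }


def coamplification_breakdown(cohort: Cohort, loci: Sequence[str]) -> ConcurrencyBreakdown:
    """Counts of any/all/exclusive/pairwise high-level amplification."""
    loci = list(loci)
    if len(loci) < 2:
        raise ValueError("need at least two loci")
    missing = [g for g in loci if g not in cohort.cn.index]
    if missing:
        raise KeyError(f"locus/loci absent from copy-number matrix: {missing}")
    amp = (cohort.cn.loc[loci] == 2).to_numpy()  # loci x samples, NA -> False
    per_sample = amp.sum(axis=0)
    return ConcurrencyBreakdown(
        loci=loci,
        n_any_amplified=int((per_sample >= 1).sum()),
        n_all_amplified=int((per_sample == len(loci)).sum()),
        exclusive={
            g: int((amp[i] & (per_sample == 1)).sum()) for i, g in enumerate(loci)
        },
        pairwise={
            (a, b): int((amp[i] & amp[j]).sum())
            for (i, a), (j, b) in combinations(enumerate(loci), 2)
        },
    )
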