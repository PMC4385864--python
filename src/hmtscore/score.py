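"""Five-criterion integrative score for candidate driver/suppressor genes.

Each gene earns one point per satisfied criterion:

1. recurrent alteration — high-level amplification >5%, homozygous
   deletion >2%, or somatic mutation >2% of tumors;
2. copy number associated with survival — minimum pairwise log-rank p
   (amp/gain vs diploid, deletion vs diploid) below 0.1;
3. dosage correlation — Spearman r > 0.5 with p < 0.001;
4. altered expression in basal-like tumors — two-group t-test p < 0.001,
   either direction;
5. expression associated with survival — median-split log-rank p below 0.1.

All thresholds are strict inequalities and configurable; scores range 0-5
and genes are ranked by score (ties broken alphabetically).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort
from .correlation import dosage_correlations
from .diffexpr import differential_table
from .landscape import alteration_frequencies, select_top_altered
from .survival import survival_association

logger = logging.getLogger(__name__)

FLAG_COLUMNS = [
    "c_alteration",
    "c_cna_survival",
    "c_dna_mrna",
    "c_expression",
    "c_mrna_survival",
]


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs of the five criteria (defaults as published)."""

    amp: float = 5.0
    homdel: float = 2.0
    mut: float = 2.0
    cna_survival_p: float = 0.1
    corr_r: float = 0.5
    corr_p: float = 0.001
    expression_p: float = 0.001
    expr_survival_p: float = 0.1


def _landscape_row(landscape: pd.DataFrame, gene: str) -> pd.Series | None:
    if isinstance(landscape.index, pd.MultiIndex):
        landscape = landscape.xs("all", level="subtype")
    if gene not in landscape.index:
        return None
    return landscape.loc[gene]


def score_genes(
    landscape: pd.DataFrame,
    correlations: pd.DataFrame,
    differentials: pd.DataFrame,
    cna_survival: Mapping[str, float],
    expr_survival: Mapping[str, float],
    thresholds: Thresholds | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score cards for every gene, ranked by descending score.

    Parameters mirror the five analysis stages: ``landscape`` carries
    ``f_amp/f_homdel/f_mut`` (percent), ``correlations`` carries
    ``r_spearman/p_spearman``, ``differentials`` carries ``p``, and the two
    survival mappings give each gene's minimum pairwise log-rank p.  A gene
    missing from a stage gets that flag False with a warning.
    """
    th = thresholds or Thresholds()
    if genes is None:
        base = landscape
        if isinstance(base.index, pd.MultiIndex):
            base = base.xs("all", level="subtype")
        genes = list(base.index)
    if len(genes) == 0:
        raise ValueError("empty gene universe")

    rows = []
    for gene in genes:
        flags = {}
        lrow = _landscape_row(landscape, gene)
        if lrow is None:
            logger.warning("gene %s missing from alteration landscape", gene)
            flags["c_alteration"] = False
        else:
            flags["c_alteration"] = bool(
                lrow["f_amp"] > th.amp
                or lrow["f_homdel"] > th.homdel
                or lrow["f_mut"] > th.mut
            )
        p = cna_survival.get(gene)
        if p is None or (isinstance(p, float) and np.isnan(p)):
            if gene not in cna_survival:
                logger.warning("gene %s missing CNA-survival result", gene)
            flags["c_cna_survival"] = False
        else:
            flags["c_cna_survival"] = bool(p < th.cna_survival_p)
        if gene in correlations.index:
            crow = correlations.loc[gene]
            flags["c_dna_mrna"] = bool(
                crow["r_spearman"] > th.corr_r and crow["p_spearman"] < th.corr_p
            )
        else:
            logger.warning("gene %s missing correlation result", gene)
            flags["c_dna_mrna"] = False
        if gene in differentials.index:
            flags["c_expression"] = bool(differentials.loc[gene, "p"] < th.expression_p)
        else:
            logger.warning("gene %s missing differential-expression result", gene)
            flags["c_expression"] = False
        p = expr_survival.get(gene)
        if p is None or (isinstance(p, float) and np.isnan(p)):
            if gene not in expr_survival:
                logger.warning("gene %s missing expression-survival result", gene)
            flags["c_mrna_survival"] = False
        else:
            flags["c_mrna_survival"] = bool(p < th.expr_survival_p)
        rows.append({"gene": gene, **flags, "score": sum(flags.values())})

    out = pd.DataFrame(rows).set_index("gene")
    # stable sorts: alphabetical first, then score desc => alphabetical ties
    return out.sort_index(kind="stable").sort_values(
        "score", ascending=False, kind="stable"
    )


def run_pipeline(
    cohort: Cohort,
    genes: Sequence[str],
    thresholds: Thresholds | None = None,
    out_dir: str | Path | None = None,
    ttest_method: str = "welch",
) -> dict:
    """Execute all stages on a cohort and assemble the ranked score table.

    Stages run in order: alteration landscape -> dosage correlation ->
    basal differential expression -> survival (copy-number groups and
    expression split) -> integrative score.  Genes for which a stage is not
    computable (no expression data, a single survival group, ...) simply
    lack that stage's entry and score zero on the affected criterion.
    Results are optionally written as TSVs plus a manifest.
    """
    th = thresholds or Thresholds()
    stage = "alteration_landscape"
    try:
        landscape = alteration_frequencies(cohort, genes)
        selected = select_top_altered(
            landscape, amp_thresh=th.amp, homdel_thresh=th.homdel, mut_thresh=th.mut
        )
    except Exception as exc:  # pragma: no cover - re-raise with stage name
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    def _per_gene(fn, label):
        results = {}
        for g in genes:
            try:
                results[g] = fn(g)
            except (KeyError, ValueError) as exc:
                logger.warning("stage %s: gene %s skipped (%s)", label, g, exc)
        return results

    corr_genes = [g for g in genes if g in cohort.expr.index]
    try:
        correlations = dosage_correlations(
            cohort, [g for g in corr_genes if g in cohort.cn.index]
        ) if corr_genes else pd.DataFrame(columns=["r_spearman", "p_spearman"])
    except Exception as exc:
        raise RuntimeError(f"stage dosage_correlation failed: {exc}") from exc

    diff_results = _per_gene(
        lambda g: differential_table(cohort, [g], method=ttest_method).iloc[0],
        "differential_expression",
    )
    differentials = (
        pd.DataFrame(diff_results).T.rename_axis("gene")
        if diff_results
        else pd.DataFrame(columns=["t_stat", "p"])
    )

    has_survival = cohort.clinical["os_months"].notna().any()
    cna_surv: dict[str, float] = {}
    expr_surv: dict[str, float] = {}
    if has_survival:
        for g, assoc in _per_gene(
            lambda g: survival_association(cohort, g, "cna"), "cna_survival"
        ).items():
            cna_surv[g] = assoc.logrank.min_pairwise_p
        for g, assoc in _per_gene(
            lambda g: survival_association(cohort, g, "expr"), "expr_survival"
        ).items():
            expr_surv[g] = assoc.logrank.min_pairwise_p
    else:
        logger.warning("no survival data in cohort; survival criteria scored False")

    scores = score_genes(
        landscape, correlations, differentials, cna_surv, expr_surv, th, genes=genes
    )
    report = {
        "landscape": landscape,
        "selected": selected,
        "correlations": correlations,
        "differentials": differentials,
        "cna_survival": cna_surv,
        "expr_survival": expr_surv,
        "scores": scores,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        landscape.round(2).to_csv(out / "alteration_landscape.tsv", sep="\t")
        selected.to_csv(out / "selected_genes.tsv", sep="\t", index=False)
        correlations.to_csv(out / "dosage_correlation.tsv", sep="\t")
        differentials.to_csv(out / "differential_expression.tsv", sep="\t")
        pd.DataFrame(
            [{"gene": g, "analysis": a, "p": p}
             for a, d in (("cna", cna_surv), ("expr", expr_surv))
             for g, p in d.items()]
        ).to_csv(out / "survival_associations.tsv", sep="\t", index=False)
        scores.to_csv(out / "integrative_scores.tsv", sep="\t")
        manifest = {
            "package_version": __version__,
            "thresholds": asdict(th),
            "ttest_method": ttest_method,
            "n_genes": len(genes),
            "n_samples": cohort.n_samples,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
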