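"""Packaged reference tables from the published TCGA breast-cancer analysis.

Three small TSVs ship with the package:

* ``cna_mutation_frequencies.tsv`` — per-gene frequencies (percent of 958
  tumors) of the five GISTIC copy-number categories and of somatic mutation,
  for the 50 histone methyltransferase genes with copy-number data.
* ``correlation_expression.tsv`` — per-gene copy-number/expression rank
  correlations (Spearman, Kendall, Pearson) and the basal-vs-non-basal
  t-statistic and p-value, for the 48 genes with RNA-seq data.
* ``survival_associations.tsv`` — per-gene log-rank p-values for the
  copy-number-group and expression-median-split survival analyses (genes
  that reached significance; see the file header for the placeholder
  convention on the copy-number rows).

These values let the integrative scorer, the threshold screens and the
synthetic-cohort generator be exercised without the original 958-sample
TCGA export.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

from .correlation import spearman_p_from_r

_DATA = files("hmtscore") / "data"

#: Number of tumors behind the packaged frequency and correlation tables.
N_TOTAL = 958
#: Tumors with molecular-subtype annotation, and the per-subtype counts.
N_SUBTYPED = 492
SUBTYPE_COUNTS = {
    "NormalLike": 8,
    "LuminalA": 220,
    "LuminalB": 121,
    "HER2": 55,
    "Basal": 88,
}
#: Tumors with overall-survival annotation.
N_SURVIVAL = 770


def _read(name: str, **kw) -> pd.DataFrame:
    with (_DATA / name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#", **kw)


def load_alteration_frequencies() -> pd.DataFrame:
    """Per-gene GISTIC-category and mutation frequencies (percent).

    Columns: ``location, f_amp, f_gain, f_diploid, f_hetloss, f_homdel,
    f_mut``; indexed by gene symbol.
    """
    return _read("cna_mutation_frequencies.tsv", index_col=0)


def load_correlation_expression(n: int = N_TOTAL) -> pd.DataFrame:
    """Correlation coefficients and basal-vs-non-basal t-test results.

    The source prints coefficients but not correlation p-values; Spearman
    p-values are recomputed here from r via the t approximation at ``n``
    pairs and exposed as ``p_spearman``.
    """
    df = _read("correlation_expression.tsv", index_col=0)
    df["p_spearman"] = [spearman_p_from_r(r, n) for r in df["r_spearman"]]
    return df


def load_survival_associations() -> pd.DataFrame:
    """Long-format survival p-values: columns gene, analysis, p, p_is_placeholder."""
    return _read("survival_associations.tsv")


def load_gene_aliases() -> pd.DataFrame:
    """Reference alias table for the 51 histone methyltransferase genes."""
    return _read("hmt_gene_aliases.tsv", index_col=0)


def survival_p_map(analysis: str) -> dict[str, float]:
    """Gene -> min pairwise log-rank p for ``analysis`` in {"cna", "expr"}.

    Genes from the frequency table absent from the survival list were not
    reported as significant; they are mapped to NaN (known, below no
    threshold) rather than omitted.
    """
    df = load_survival_associations()
    sel = df[df["analysis"] == analysis]
    out = {g: float("nan") for g in load_alteration_frequencies().index}
    out.update(zip(sel["gene"], sel["p"]))
    return out


def fixture_score_inputs() -> dict:
    """The five stage outputs needed by the integrative scorer, from fixtures.

    Returns a dict with keys ``landscape`` (frequency DataFrame),
    ``correlations``, ``differentials`` (both gene-indexed DataFrames) and
    ``cna_survival`` / ``expr_survival`` (gene -> p mappings).
    """
    corr = load_correlation_expression()
    return {
        "landscape": load_alteration_frequencies(),
        "correlations": corr[["r_spearman", "p_spearman"]],
        "differentials": corr[["t_stat", "p_value"]].rename(
            columns={"p_value": "p"}
        ),
        "cna_survival": survival_p_map("cna"),
        "expr_survival": survival_p_map("expr"),
    }


def write_fixture_files(out_dir: str | Path) -> list[Path]:
    """Copy the packaged reference TSVs into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in (
        "cna_mutation_frequencies.tsv",
        "correlation_expression.tsv",
        "survival_associations.tsv",
        "hmt_gene_aliases.tsv",
    ):
        dest = out / name
        dest.write_text((_DATA / name).read_text(encoding="utf-8"), encoding="utf-8")
        written.append(dest)
    return written
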