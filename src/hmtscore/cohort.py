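"""Cohort data model and tab-delimited I/O.

A breast-cancer cohort is four aligned tables over a shared sample universe:

* gene x sample putative copy-number calls (GISTIC categories -2..+2),
* gene x sample mRNA expression z-scores,
* a per-mutation table (sample, gene, protein change, mutation type),
* a per-sample clinical table (molecular subtype, overall survival,
  standard prognostic markers).

Matrices are stored as :class:`pandas.DataFrame` with gene symbols as the
index and sample identifiers as columns; missing entries are ``NA``.  The
sample universe is the union of sample identifiers seen in any table —
samples present in some tables but not others are retained with missing
fields, and each analysis stage applies its own complete-case rule.

The file dialect is fixed: tab-delimited UTF-8, first row sample IDs,
first column gene symbol, missing values written as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: GISTIC putative copy-number categories.
GISTIC_CALLS = (-2, -1, 0, 1, 2)

#: PAM50-style molecular subtypes plus the "unknown" marker.
SUBTYPES = ("LuminalA", "LuminalB", "HER2", "Basal", "NormalLike")
UNKNOWN_SUBTYPE = "unknown"

#: Canonical mutation-type vocabulary.
MUTATION_TYPES = (
    "missense",
    "nonsense",
    "frameshift_del",
    "frameshift_ins",
    "splice",
    "inframe_ins",
    "inframe_del",
)

#: Case-insensitive normalization of common MAF ``Variant_Classification``
#: spellings.  A value of ``None`` means the record is silent/non-coding and
#: is dropped at parse time.
DEFAULT_MUTATION_TYPE_MAP: dict[str, str | None] = {
    "missense": "missense",
    "missense_mutation": "missense",
    "nonsense": "nonsense",
    "nonsense_mutation": "nonsense",
    "frameshift_del": "frameshift_del",
    "frame_shift_del": "frameshift_del",
    "frameshift_deletion": "frameshift_del",
    "frameshift_ins": "frameshift_ins",
    "frame_shift_ins": "frameshift_ins",
    "frameshift_insertion": "frameshift_ins",
    "splice": "splice",
    "splice_site": "splice",
    "splice_region": "splice",
    "inframe_ins": "inframe_ins",
    "in_frame_ins": "inframe_ins",
    "inframe_insertion": "inframe_ins",
    "inframe_del": "inframe_del",
    "in_frame_del": "inframe_del",
    "inframe_deletion": "inframe_del",
    "silent": None,
    "synonymous": None,
    "rna": None,
    "intron": None,
    "3'utr": None,
    "5'utr": None,
    "igr": None,
}

MUTATION_COLUMNS = ["sample_id", "gene", "protein_change", "mutation_type", "position"]
CLINICAL_COLUMNS = [
    "subtype",
    "os_months",
    "os_event",
    "age_years",
    "er",
    "pr",
    "her2",
    "tumor_size",
    "node_status",
    "metastasis_status",
]

NA_REP = "NA"


class CohortValidationError(ValueError):
    """Raised when a cohort table violates a structural invariant."""


@dataclass
class Cohort:
    """Aligned copy-number, expression, mutation and clinical tables.

    Attributes
    ----------
    cn:
        Copy-number calls, gene x sample, nullable integer in {-2..2}.
    expr:
        Expression z-scores, gene x sample, float with NaN for missing.
    mutations:
        One row per mutation record with columns
        ``sample_id, gene, protein_change, mutation_type, position``.
    clinical:
        One row per sample (indexed by sample_id) with columns
        ``subtype, os_months, os_event, age_years, er, pr, her2,
        tumor_size, node_status, metastasis_status``.
    samples:
        The declared sample universe (union of samples across tables).
    """

    cn: pd.DataFrame
    expr: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = sorted(
                set(self.cn.columns)
                | set(self.expr.columns)
                | set(self.mutations["sample_id"].astype(str))
                | set(self.clinical.index.astype(str))
            )
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        universe = set(self.samples)
        for name, mat in (("copy-number", self.cn), ("expression", self.expr)):
            if mat.index.duplicated().any():
                dupes = mat.index[mat.index.duplicated()].unique().tolist()
                raise CohortValidationError(
                    f"duplicate gene symbol(s) in {name} matrix: {dupes}"
                )
            if mat.columns.duplicated().any():
                dupes = mat.columns[mat.columns.duplicated()].unique().tolist()
                raise CohortValidationError(
                    f"duplicate sample id(s) in {name} matrix: {dupes}"
                )
            extra = set(mat.columns) - universe
            if extra:
                raise CohortValidationError(
                    f"{name} matrix has samples outside the universe: {sorted(extra)}"
                )
        _validate_calls(self.cn)
        bad_expr = ~np.isfinite(self.expr.to_numpy(dtype=float))
        bad_expr &= ~self.expr.isna().to_numpy(dtype=bool)
        if bad_expr.any():
            raise CohortValidationError("non-finite expression value present")
        bad_types = set(self.mutations["mutation_type"]) - set(MUTATION_TYPES)
        if bad_types:
            raise CohortValidationError(
                f"unknown mutation_type(s) {sorted(bad_types)}; "
                f"accepted: {list(MUTATION_TYPES)}"
            )
        pos = self.mutations["position"]
        if ((pos.dropna() < 1)).any():
            raise CohortValidationError("mutation position must be >= 1")
        extra = set(self.mutations["sample_id"]) - universe
        if extra:
            raise CohortValidationError(
                f"mutation sample id(s) outside the universe: {sorted(extra)}"
            )
        extra = set(self.clinical.index) - universe
        if extra:
            raise CohortValidationError(
                f"clinical sample id(s) outside the universe: {sorted(extra)}"
            )
        known = set(SUBTYPES) | {UNKNOWN_SUBTYPE}
        bad = set(self.clinical["subtype"].dropna()) - known
        if bad:
            raise CohortValidationError(f"unknown subtype value(s): {sorted(bad)}")
        has_t = self.clinical["os_months"].notna()
        has_e = self.clinical["os_event"].notna()
        if (has_t ^ has_e).any():
            raise CohortValidationError(
                "os_event must be present exactly when os_months is present"
            )

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def clinical_record(self, sample_id: str) -> pd.Series:
        """Clinical record for a sample; all-missing if not annotated."""
        if sample_id in self.clinical.index:
            return self.clinical.loc[sample_id]
        return pd.Series(
            {c: (UNKNOWN_SUBTYPE if c == "subtype" else np.nan) for c in CLINICAL_COLUMNS},
            name=sample_id,
        )

    def equals(self, other: "Cohort") -> bool:
        mut_a = self.mutations.reset_index(drop=True)
        mut_b = other.mutations.reset_index(drop=True)
        return (
            list(self.samples) == list(other.samples)
            and self.cn.equals(other.cn)
            and _frames_close(self.expr, other.expr)
            and mut_a.equals(mut_b)
            and _frames_equal_mixed(self.clinical, other.clinical)
        )


def _frames_close(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if a.shape != b.shape or list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        return False
    x, y = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    both_nan = np.isnan(x) & np.isnan(y)
    return bool(np.all(both_nan | np.isclose(x, y, rtol=0, atol=1e-9)))


def _frames_equal_mixed(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if a.shape != b.shape or list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        return False
    for col in a.columns:
        x, y = a[col], b[col]
        if pd.api.types.is_numeric_dtype(x) and pd.api.types.is_numeric_dtype(y):
            xv, yv = x.to_numpy(dtype=float), y.to_numpy(dtype=float)
            ok = np.all((np.isnan(xv) & np.isnan(yv)) | np.isclose(xv, yv, rtol=0, atol=1e-9))
        else:
            ok = x.fillna(NA_REP).astype(str).equals(y.fillna(NA_REP).astype(str))
        if not ok:
            return False
    return True


def _validate_calls(cn: pd.DataFrame) -> None:
    arr = cn.to_numpy(dtype=float)
    bad = ~np.isin(arr, GISTIC_CALLS) & ~np.isnan(arr)
    if bad.any():
        gi, si = map(int, np.argwhere(bad)[0])
        raise CohortValidationError(
            f"invalid copy-number call {arr[gi, si]!r} for gene "
            f"{cn.index[gi]!r}, sample {cn.columns[si]!r}; "
            f"allowed: {list(GISTIC_CALLS)} or {NA_REP}"
        )


# ---------------------------------------------------------------------------
# reading


def _read_matrix(path: str | Path, dtype: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP], keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df.columns = df.columns.astype(str)
    return df.astype(dtype)


def normalize_mutation_types(
    raw: Iterable[str], type_map: Mapping[str, str | None] | None = None
) -> list[str | None]:
    """Map raw variant-classification strings onto the canonical vocabulary.

    Unknown spellings raise; spellings mapped to ``None`` (silent etc.) are
    returned as ``None`` so callers can drop the records.
    """
    tmap = dict(DEFAULT_MUTATION_TYPE_MAP)
    if type_map:
        tmap.update({k.lower(): v for k, v in type_map.items()})
    out: list[str | None] = []
    for value in raw:
        key = str(value).strip().lower()
        if key not in tmap:
            raise CohortValidationError(
                f"unknown mutation type {value!r}; accepted spellings: "
                f"{sorted(k for k in tmap if tmap[k] is not None)}"
            )
        out.append(tmap[key])
    return out


def parse_protein_position(protein_change: str) -> float:
    """Leading amino-acid coordinate of an HGVS-short string.

    The first run of digits is taken as the residue number
    (``"D3264N"`` -> 3264, ``"Q1218*"`` -> 1218, ``"p.K100del"`` -> 100);
    NaN when no digits are present.
    """
    import re

    m = re.search(r"\d+", str(protein_change))
    return float(m.group()) if m else np.nan


def _read_mutations(path: str | Path, type_map=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False,
                     comment="#", dtype=str)
    maf_cols = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    if maf_cols.issubset(df.columns):
        df = df.rename(
            columns={
                "Hugo_Symbol": "gene",
                "Tumor_Sample_Barcode": "sample_id",
                "Variant_Classification": "mutation_type",
                "HGVSp_Short": "protein_change",
            }
        )
    if "protein_change" not in df.columns:
        df["protein_change"] = ""
    missing = {"sample_id", "gene", "mutation_type"} - set(df.columns)
    if missing:
        raise CohortValidationError(f"mutation table lacks column(s): {sorted(missing)}")
    df["mutation_type"] = normalize_mutation_types(df["mutation_type"], type_map)
    n_silent = df["mutation_type"].isna().sum()
    if n_silent:
        logger.info("dropping %d silent/non-coding mutation record(s)", n_silent)
        df = df[df["mutation_type"].notna()]
    df["protein_change"] = df["protein_change"].fillna("")
    df["position"] = df["protein_change"].map(parse_protein_position)
    return df[MUTATION_COLUMNS].reset_index(drop=True)


def _read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP], keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["subtype"] = df["subtype"].fillna(UNKNOWN_SUBTYPE).astype(str)
    for col in ("os_months", "os_event", "age_years", "tumor_size",
                "node_status", "metastasis_status"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("er", "pr", "her2"):
        df[col] = df[col].fillna("unknown").astype(str)
    return df[CLINICAL_COLUMNS]


def read_cohort(
    cn_path: str | Path,
    expr_path: str | Path,
    mut_path: str | Path,
    clinical_path: str | Path,
    config: Mapping | None = None,
) -> Cohort:
    """Read and validate the four cohort tables.

    ``config`` may carry ``mutation_type_map`` (extra spellings) — see
    :data:`DEFAULT_MUTATION_TYPE_MAP`.
    """
    config = dict(config or {})
    cn = _read_matrix(cn_path, "Int64")
    expr = _read_matrix(expr_path, "float64")
    mutations = _read_mutations(mut_path, config.get("mutation_type_map"))
    clinical = _read_clinical(clinical_path)
    cohort = Cohort(cn=cn, expr=expr, mutations=mutations, clinical=clinical)
    logger.info(
        "cohort: %d samples | cn %dx%d (%d missing) | expr %dx%d (%d missing) "
        "| %d mutation records | %d clinical records",
        cohort.n_samples,
        *cn.shape, int(cn.isna().sum().sum()),
        *expr.shape, int(expr.isna().sum().sum()),
        len(mutations), len(clinical),
    )
    return cohort


# ---------------------------------------------------------------------------
# writing


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables in the dialect :func:`read_cohort` accepts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cn": out / "copy_number.tsv",
        "expr": out / "expression.tsv",
        "mutations": out / "mutations.tsv",
        "clinical": out / "clinical.tsv",
    }
    cohort.cn.to_csv(paths["cn"], sep="\t", na_rep=NA_REP)
    cohort.expr.to_csv(paths["expr"], sep="\t", na_rep=NA_REP)
    mut = cohort.mutations.copy()
    mut["position"] = mut["position"].astype("Int64")
    mut.to_csv(paths["mutations"], sep="\t", index=False, na_rep=NA_REP)
    clin = cohort.clinical.copy()
    clin["os_event"] = clin["os_event"].astype("Int64")
    clin.to_csv(paths["clinical"], sep="\t", na_rep=NA_REP)
    return paths


# ---------------------------------------------------------------------------
# subsetting


def subset_samples(cohort: Cohort, predicate: Callable[[pd.Series], bool]) -> Cohort:
    """Restrict all four tables to samples whose clinical record matches.

    The predicate receives one :class:`pandas.Series` per sample in the
    universe (all-missing for samples without a clinical row).  An empty
    match yields an empty cohort with a warning, not an error.
    """
    keep = [s for s in cohort.samples if bool(predicate(cohort.clinical_record(s)))]
    if not keep:
        logger.warning("subset_samples: predicate matched no samples")
    keep_set = set(keep)
    sub = Cohort(
        cn=cohort.cn.loc[:, [c for c in cohort.cn.columns if c in keep_set]],
        expr=cohort.expr.loc[:, [c for c in cohort.expr.columns if c in keep_set]],
        mutations=cohort.mutations[
            cohort.mutations["sample_id"].isin(keep_set)
        ].reset_index(drop=True),
        clinical=cohort.clinical.loc[[s for s in cohort.clinical.index if s in keep_set]],
        samples=keep,
    )
    logger.info("subset_samples: kept %d of %d samples", len(keep), cohort.n_samples)
    return sub
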