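"""Overall-survival association analyses.

Samples are grouped either by copy-number state — amp/gain ({+1,+2}),
diploid ({0}), deletion ({-1,-2}) — or by a median split of the expression
z-score (ties at the median go to the low group).  Group differences are
assessed with the log-rank test (omnibus over all groups, plus pairwise
tests against the reference group), hazard ratios come from univariate Cox
fits, and a multivariate Cox proportional-hazards model adjusts the gene
exposure for the standard clinical prognostic markers.  Fitting is done
with lifelines (Efron handling of tied event times).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .cohort import Cohort

logger = logging.getLogger(__name__)

CNA_GROUPS = ("amp_gain", "diploid", "deletion")
EXPR_GROUPS = ("low", "high")

#: Default covariates of the multivariate model.
DEFAULT_COVARIATES = (
    "age_years",
    "er",
    "pr",
    "her2",
    "tumor_size",
    "node_status",
    "metastasis_status",
    "basal",
)


@dataclass
class LogrankResult:
    chi2: float
    p: float
    df: int
    pairwise: dict[str, float]  # group -> p vs the reference group
    group_sizes: dict[str, int]

    @property
    def min_pairwise_p(self) -> float:
        return min(self.pairwise.values()) if self.pairwise else np.nan


@dataclass
class HazardRatio:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool = True


@dataclass
class SurvivalAssociation:
    gene: str
    analysis: str  # "cna_groups" | "expr_split"
    logrank: LogrankResult
    hr: HazardRatio | None = None


@dataclass
class CoxFit:
    coefficients: pd.DataFrame  # index covariate; columns coef, se, p, hr
    n_used: int
    converged: bool


# ---------------------------------------------------------------------------
# grouping


def _survival_frame(cohort: Cohort) -> pd.DataFrame:
    """time/event per sample, restricted to positive follow-up times."""
    clin = cohort.clinical
    ok = clin["os_months"].notna()
    df = clin.loc[ok, ["os_months", "os_event"]].astype(float)
    nonpos = df["os_months"] <= 0
    if nonpos.any():
        logger.warning("dropping %d sample(s) with non-positive follow-up", int(nonpos.sum()))
        df = df[~nonpos]
    return df.rename(columns={"os_months": "time", "os_event": "event"})


def cna_groups(cohort: Cohort, gene: str) -> pd.Series:
    """amp_gain / diploid / deletion labels over survival-evaluable samples."""
    if gene not in cohort.cn.index:
        raise KeyError(f"gene {gene!r} not in copy-number matrix")
    surv = _survival_frame(cohort)
    calls = cohort.cn.loc[gene].reindex(surv.index).astype(float)
    labels = pd.Series(index=surv.index, dtype=object, name="group")
    labels[calls.isin([1, 2])] = "amp_gain"
    labels[calls == 0] = "diploid"
    labels[calls.isin([-1, -2])] = "deletion"
    return labels.dropna()


def median_split(cohort: Cohort, gene: str) -> pd.Series:
    """low/high labels by the expression median; ties go to low."""
    if gene not in cohort.expr.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    surv = _survival_frame(cohort)
    z = cohort.expr.loc[gene].reindex(surv.index).astype(float).dropna()
    if len(z) < 2:
        raise ValueError(f"gene {gene!r}: fewer than 2 expression+survival samples")
    if np.ptp(z.to_numpy()) == 0:
        raise ValueError(f"gene {gene!r}: constant expression, no split possible")
    med = float(z.median())
    labels = pd.Series(np.where(z <= med, "low", "high"), index=z.index, name="group")
    logger.info(
        "median split for %s: low=%d high=%d", gene,
        int((labels == "low").sum()), int((labels == "high").sum()),
    )
    return labels


# ---------------------------------------------------------------------------
# estimators


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Product-limit survival estimate: columns time, survival, at_risk."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one sample")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    out = kmf.survival_function_.reset_index()
    out.columns = ["time", "survival"]
    at_risk = kmf.event_table["at_risk"].reindex(out["time"]).to_numpy()
    out["at_risk"] = at_risk
    return out


def logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
    reference: str | None = None,
) -> LogrankResult:
    """Omnibus log-rank over all groups plus pairwise tests vs reference."""
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "group": np.asarray(groups, dtype=object),
    })
    sizes = df["group"].value_counts().to_dict()
    if len(sizes) < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    if df["event"].sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    if reference is None:
        reference = "diploid" if "diploid" in sizes else "low" if "low" in sizes else sorted(sizes)[0]
    pairwise = {}
    ref = df[df["group"] == reference]
    for g in sorted(sizes):
        if g == reference:
            continue
        other = df[df["group"] == g]
        pw = logrank_test(ref["time"], other["time"], ref["event"], other["event"])
        pairwise[g] = float(pw.p_value)
    return LogrankResult(
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        df=len(sizes) - 1,
        pairwise=pairwise,
        group_sizes={k: int(v) for k, v in sizes.items()},
    )


def univariate_hr(
    times: Sequence[float], events: Sequence[int], exposure: Sequence[int]
) -> HazardRatio:
    """Hazard ratio of exposure=1 vs 0 from a single-covariate Cox fit."""
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "x": np.asarray(exposure, dtype=float),
    })
    if df.groupby("x")["event"].sum().min() < 1:
        logger.warning("a group has no events; hazard ratio may be unstable")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        logger.warning("univariate Cox did not converge (monotone likelihood?)")
        return HazardRatio(np.nan, 0.0, np.inf, np.nan, converged=False)
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return HazardRatio(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=float(cph.summary.loc["x", "p"]),
    )


def survival_association(cohort: Cohort, gene: str, mode: str) -> SurvivalAssociation:
    """Log-rank (omnibus + pairwise) and, for the expression split, the HR.

    ``mode`` is ``"cna"`` (three copy-number groups, diploid reference) or
    ``"expr"`` (median split, low reference; HR of high vs low).
    """
    if mode not in ("cna", "expr"):
        raise ValueError("mode must be 'cna' or 'expr'")
    labels = cna_groups(cohort, gene) if mode == "cna" else median_split(cohort, gene)
    surv = _survival_frame(cohort).reindex(labels.index)
    lr = logrank(surv["time"], surv["event"], labels)
    hr = None
    if mode == "expr":
        hr = univariate_hr(surv["time"], surv["event"], (labels == "high").astype(int))
    return SurvivalAssociation(
        gene=gene,
        analysis="cna_groups" if mode == "cna" else "expr_split",
        logrank=lr,
        hr=hr,
    )


# ---------------------------------------------------------------------------
# multivariate Cox


def _encode_covariates(cohort: Cohort) -> pd.DataFrame:
    clin = cohort.clinical
    enc = pd.DataFrame(index=clin.index)
    enc["age_years"] = pd.to_numeric(clin["age_years"], errors="coerce")
    for col in ("er", "pr", "her2"):
        enc[col] = clin[col].map({"pos": 1.0, "neg": 0.0})
    for col in ("tumor_size", "node_status", "metastasis_status"):
        enc[col] = pd.to_numeric(clin[col], errors="coerce")
    st = clin["subtype"]
    enc["basal"] = np.where(st == "Basal", 1.0,
                            np.where(st.isin(["LuminalA", "LuminalB", "HER2", "NormalLike"]),
                                     0.0, np.nan))
    return enc


def cox_multivariate(
    cohort: Cohort,
    gene: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    exposure: str = "cna",
) -> CoxFit:
    """Cox PH fit of the gene exposure adjusted for clinical covariates.

    ``exposure="cna"`` enters amp/gain and deletion indicators (diploid
    reference); ``exposure="expr"`` enters the high-expression indicator.
    Complete cases over time, event, exposure and all covariates are used.
    """
    surv = _survival_frame(cohort)
    if exposure == "cna":
        labels = cna_groups(cohort, gene)
        xmat = pd.DataFrame({
            f"{gene}_amp_gain": (labels == "amp_gain").astype(float),
            f"{gene}_deletion": (labels == "deletion").astype(float),
        })
    elif exposure == "expr":
        labels = median_split(cohort, gene)
        xmat = pd.DataFrame({f"{gene}_high": (labels == "high").astype(float)})
    else:
        raise ValueError("exposure must be 'cna' or 'expr'")
    enc = _encode_covariates(cohort)
    df = surv.join(xmat, how="inner").join(enc[list(covariates)], how="left").dropna()
    design = df.drop(columns=["time", "event"])
    # drop constant columns (e.g. an exposure level absent after complete-case)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant covariate(s): %s", constant)
        design = design.drop(columns=constant)
        df = df.drop(columns=constant)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = design.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = corr.stack().idxmax()
        raise ValueError(f"singular design matrix; collinear columns include {pair}")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        logger.warning("multivariate Cox did not converge for %s", gene)
        return CoxFit(coefficients=pd.DataFrame(), n_used=len(df), converged=False)
    coefs = pd.DataFrame({
        "coef": cph.params_,
        "se": cph.standard_errors_,
        "p": cph.summary["p"],
        "hr": np.exp(cph.params_),
    })
    return CoxFit(coefficients=coefs, n_used=len(df), converged=True)
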