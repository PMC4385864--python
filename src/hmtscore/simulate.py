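"""Synthetic TCGA-like breast-cancer cohorts with controlled structure.

The generator emulates the joint structure the downstream stages consume:

* per-gene multinomial GISTIC copy-number calls, optionally
  subtype-stratified;
* expression z-scores linearly coupled to the call
  (``z = beta * call + delta_basal * 1[basal] + N(0, sigma)``, then
  standardized), so the call/expression rank correlation is tunable
  through ``beta / sigma``;
* per-gene somatic mutations with multiple hits per sample (the hit count
  is Poisson with rate ``-log(1 - p)`` so the per-sample probability of at
  least one hit equals ``p`` exactly);
* exponential survival times with group-specific log-hazard effects and
  independent uniform censoring.

Subtype membership and survival annotation use exact largest-remainder
allocation of ``n * weight`` (then a seeded shuffle), so cohort-level
counts such as 492/958 subtyped and 770/958 survival-annotated are
reproduced exactly while all per-sample values remain stochastic.
Randomness is split into per-table, per-gene substreams keyed by stable
string tags, so adding a gene to a spec does not perturb the columns of
existing genes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, GISTIC_CALLS, MUTATION_TYPES, SUBTYPES, UNKNOWN_SUBTYPE

_DEFAULT_TYPE_PROBS = {
    "missense": 0.45,
    "nonsense": 0.2,
    "frameshift_del": 0.15,
    "frameshift_ins": 0.1,
    "splice": 0.05,
    "inframe_ins": 0.03,
    "inframe_del": 0.02,
}

_PROTEIN_CHANGE_FMT = {
    "missense": "A{pos}V",
    "nonsense": "Q{pos}*",
    "frameshift_del": "K{pos}fs",
    "frameshift_ins": "K{pos}fs",
    "splice": "X{pos}_splice",
    "inframe_ins": "K{pos}ins",
    "inframe_del": "K{pos}del",
}


@dataclass
class CNASpec:
    """Multinomial category probabilities over the five GISTIC calls."""

    probs: Mapping[int, float]
    per_subtype: Mapping[str, Mapping[int, float]] | None = None

    def validate(self) -> None:
        for label, p in [("overall", self.probs)] + list((self.per_subtype or {}).items()):
            vec = np.array([p.get(c, 0.0) for c in GISTIC_CALLS], dtype=float)
            if (vec < 0).any() or (vec > 1).any() or not np.isclose(vec.sum(), 1.0, atol=1e-6):
                raise ValueError(f"CNA probabilities ({label}) must be in [0,1] and sum to 1")


@dataclass
class ExprSpec:
    """Linear dosage coupling: slope beta, noise sd sigma, basal shift."""

    beta: float = 1.0
    sigma: float = 1.0
    delta_basal: float = 0.0

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class MutSpec:
    """Per-sample mutation probability and hit characteristics."""

    rate: float = 0.0  # P(sample carries >= 1 mutation)
    type_probs: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_TYPE_PROBS))
    protein_length: int = 1000

    def validate(self) -> None:
        if not 0 <= self.rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")
        vec = np.array([self.type_probs.get(t, 0.0) for t in MUTATION_TYPES])
        if (vec < 0).any() or not np.isclose(vec.sum(), 1.0, atol=1e-6):
            raise ValueError("mutation type probabilities must sum to 1")
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")


@dataclass
class SurvSpec:
    """Exponential survival with group effects and uniform censoring.

    ``baseline_hazard`` is the per-month event rate of the reference
    group; ``effect_gene``/``group_effects`` shift the log-hazard by the
    sample's copy-number group (amp_gain/diploid/deletion) for that gene;
    ``basal_loghazard`` shifts it for basal-like samples.  Censoring times
    are independent Uniform(0, max_follow_up); ``coverage`` is the
    fraction of samples with survival annotation at all.
    """

    baseline_hazard: float = 0.005
    max_follow_up: float = 240.0
    coverage: float = 1.0
    effect_gene: str | None = None
    group_effects: Mapping[str, float] = field(default_factory=dict)
    basal_loghazard: float = 0.0

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.max_follow_up <= 0:
            raise ValueError("max_follow_up must be positive")
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must be in [0, 1]")


@dataclass
class SimulationSpec:
    """Full description of a synthetic cohort."""

    n_samples: int
    subtype_weights: Mapping[str, float]
    cna: Mapping[str, CNASpec]
    expr: Mapping[str, ExprSpec] = field(default_factory=dict)
    mut: Mapping[str, MutSpec] = field(default_factory=dict)
    surv: SurvSpec = field(default_factory=SurvSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        w = np.array(list(self.subtype_weights.values()), dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-6):
            raise ValueError("subtype weights must be non-negative and sum to 1")
        unknown = set(self.subtype_weights) - set(SUBTYPES) - {UNKNOWN_SUBTYPE}
        if unknown:
            raise ValueError(f"unknown subtype label(s) in weights: {sorted(unknown)}")
        for g, spec in self.cna.items():
            spec.validate()
        for g, spec in self.expr.items():
            spec.validate()
        for g, spec in self.mut.items():
            spec.validate()
        self.surv.validate()


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(tag.encode())]))


def _exact_allocation(n: int, weights: Mapping[str, float]) -> list[str]:
    """Largest-remainder allocation of n slots to the weighted labels."""
    labels = list(weights)
    raw = np.array([weights[k] * n for k in labels], dtype=float)
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    out: list[str] = []
    for lab, k in zip(labels, base):
        out.extend([lab] * int(k))
    return out


def simulate_cohort(spec: SimulationSpec) -> Cohort:
    """Draw a cohort from the spec; reproducible given ``spec.seed``."""
    spec.validate()
    n = spec.n_samples
    samples = [f"S{i:05d}" for i in range(n)]

    # subtype labels: exact counts, shuffled
    labels = np.array(_exact_allocation(n, spec.subtype_weights), dtype=object)
    _rng(spec.seed, "subtype").shuffle(labels)
    basal = labels == "Basal"

    genes = sorted(set(spec.cna) | set(spec.expr) | set(spec.mut))

    # copy-number calls
    call_rows = {}
    calls_arr = {}
    for g in genes:
        cspec = spec.cna.get(g)
        if cspec is None:
            continue
        rng = _rng(spec.seed, f"cna:{g}")
        calls = np.empty(n, dtype=int)
        if cspec.per_subtype:
            for st in np.unique(labels):
                idx = np.flatnonzero(labels == st)
                p = cspec.per_subtype.get(str(st), cspec.probs)
                vec = np.array([p.get(c, 0.0) for c in GISTIC_CALLS], dtype=float)
                calls[idx] = rng.choice(GISTIC_CALLS, size=len(idx), p=vec / vec.sum())
        else:
            vec = np.array([cspec.probs.get(c, 0.0) for c in GISTIC_CALLS], dtype=float)
            calls = rng.choice(GISTIC_CALLS, size=n, p=vec / vec.sum())
        call_rows[g] = calls
        calls_arr[g] = calls
    cn = pd.DataFrame.from_dict(call_rows, orient="index", columns=samples).astype("Int64")
    cn.index.name = "gene"

    # expression coupled to dosage
    expr_rows = {}
    for g in genes:
        espec = spec.expr.get(g)
        if espec is None:
            continue
        rng = _rng(spec.seed, f"expr:{g}")
        dose = calls_arr.get(g, np.zeros(n))
        z = espec.beta * np.asarray(dose, dtype=float)
        z += espec.delta_basal * basal.astype(float)
        z += rng.normal(0.0, espec.sigma, size=n)
        sd = z.std()
        expr_rows[g] = (z - z.mean()) / sd if sd > 0 else z - z.mean()
    expr = pd.DataFrame.from_dict(expr_rows, orient="index", columns=samples, dtype=float)
    expr.index.name = "gene"

    # mutations: Poisson hit counts with P(>=1) == rate
    mut_records = []
    for g in genes:
        mspec = spec.mut.get(g)
        if mspec is None or mspec.rate == 0:
            continue
        rng = _rng(spec.seed, f"mut:{g}")
        counts = rng.poisson(-np.log1p(-mspec.rate), size=n)
        type_p = np.array([mspec.type_probs.get(t, 0.0) for t in MUTATION_TYPES])
        type_p = type_p / type_p.sum()
        for i in np.flatnonzero(counts):
            for _ in range(int(counts[i])):
                mtype = MUTATION_TYPES[rng.choice(len(MUTATION_TYPES), p=type_p)]
                pos = int(rng.integers(1, mspec.protein_length + 1))
                mut_records.append({
                    "sample_id": samples[i],
                    "gene": g,
                    "protein_change": _PROTEIN_CHANGE_FMT[mtype].format(pos=pos),
                    "mutation_type": mtype,
                    "position": float(pos),
                })
    mutations = pd.DataFrame(
        mut_records, columns=["sample_id", "gene", "protein_change", "mutation_type", "position"]
    )

    # survival + clinical covariates
    rng = _rng(spec.seed, "survival")
    annotated = np.array(
        _exact_allocation(n, {"yes": spec.surv.coverage, "no": 1 - spec.surv.coverage})
    ) == "yes"
    _rng(spec.seed, "survival-coverage").shuffle(annotated)
    loghaz = np.full(n, np.log(spec.surv.baseline_hazard))
    if spec.surv.effect_gene is not None:
        calls = np.asarray(calls_arr[spec.surv.effect_gene], dtype=int)
        group = np.where(calls >= 1, "amp_gain", np.where(calls == 0, "diploid", "deletion"))
        for gname, eff in spec.surv.group_effects.items():
            loghaz[group == gname] += eff
    loghaz += spec.surv.basal_loghazard * basal.astype(float)
    event_time = rng.exponential(1.0 / np.exp(loghaz))
    censor_time = rng.uniform(0.0, spec.surv.max_follow_up, size=n)
    os_months = np.minimum(event_time, censor_time)
    os_months = np.maximum(os_months, 1e-3)  # keep follow-up strictly positive
    os_event = (event_time <= censor_time).astype(float)
    os_months_col = np.where(annotated, np.round(os_months, 2), np.nan)
    os_event_col = np.where(annotated, os_event, np.nan)

    crng = _rng(spec.seed, "clinical")
    age = np.clip(crng.normal(58, 12, size=n).round(1), 25, 90)
    er = np.where(basal, crng.choice(["pos", "neg"], size=n, p=[0.1, 0.9]),
                  crng.choice(["pos", "neg"], size=n, p=[0.8, 0.2]))
    pr = np.where(basal, crng.choice(["pos", "neg"], size=n, p=[0.1, 0.9]),
                  crng.choice(["pos", "neg"], size=n, p=[0.7, 0.3]))
    her2 = np.where(labels == "HER2", crng.choice(["pos", "neg"], size=n, p=[0.9, 0.1]),
                    crng.choice(["pos", "neg"], size=n, p=[0.1, 0.9]))
    clinical = pd.DataFrame({
        "subtype": labels,
        "os_months": os_months_col,
        "os_event": os_event_col,
        "age_years": age,
        "er": er,
        "pr": pr,
        "her2": her2,
        "tumor_size": crng.integers(1, 5, size=n).astype(float),
        "node_status": crng.integers(0, 4, size=n).astype(float),
        "metastasis_status": crng.integers(0, 2, size=n).astype(float),
    }, index=pd.Index(samples, name="sample_id"))

    return Cohort(cn=cn, expr=expr, mutations=mutations, clinical=clinical, samples=samples)


def paper_like_spec(
    n_samples: int | None = None,
    seed: int = 0,
    beta: float = 1.0,
    sigma: float = 1.0,
) -> SimulationSpec:
    """A spec matching the published cohort's marginal structure.

    Subtype proportions follow the 492-of-958 subtyped breakdown
    (8 normal-like, 220 Luminal A, 121 Luminal B, 55 HER2+, 88 basal-like;
    the remainder unannotated), per-gene copy-number category and mutation
    frequencies follow the packaged frequency table, and survival
    annotation covers 770/958 of samples.  ``beta``/``sigma`` set the
    uniform dosage-expression coupling.
    """
    from .fixtures import (
        N_SURVIVAL,
        N_TOTAL,
        SUBTYPE_COUNTS,
        load_alteration_frequencies,
    )

    if n_samples is None:
        n_samples = N_TOTAL
    freq = load_alteration_frequencies()
    weights = {st: c / N_TOTAL for st, c in SUBTYPE_COUNTS.items()}
    weights[UNKNOWN_SUBTYPE] = 1.0 - sum(weights.values())
    cna, expr, mut = {}, {}, {}
    col_for_call = {2: "f_amp", 1: "f_gain", 0: "f_diploid", -1: "f_hetloss", -2: "f_homdel"}
    for gene, row in freq.iterrows():
        raw = {c: row[col] / 100.0 for c, col in col_for_call.items()}
        total = sum(raw.values())  # printed percentages carry rounding error
        cna[gene] = CNASpec(probs={c: v / total for c, v in raw.items()})
        expr[gene] = ExprSpec(beta=beta, sigma=sigma)
        mut[gene] = MutSpec(rate=row["f_mut"] / 100.0, protein_length=2000)
    return SimulationSpec(
        n_samples=n_samples,
        subtype_weights=weights,
        cna=cna,
        expr=expr,
        mut=mut,
        surv=SurvSpec(coverage=N_SURVIVAL / N_TOTAL),
        seed=seed,
    )
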