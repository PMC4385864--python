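"""Per-gene mutation spectrum and protein-domain localization.

The spectrum counts mutation *records* by type and tallies how many
mutations each sample carries (multiple hits per sample are common in the
large KMT2C/KMT2D genes); the alteration landscape, in contrast, counts
mutated *samples*.  Both statistics are exposed and never conflated.

Localization assigns each mutation's leading amino-acid coordinate (parsed
from the HGVS-short protein change, e.g. ``D3264N`` -> 3264) to every
overlapping protein domain, with inclusive 1-based bounds; positions
falling in no domain go to an inter-domain bin and records without a
parseable position are counted separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import MUTATION_TYPES

logger = logging.getLogger(__name__)


@dataclass
class SpectrumSummary:
    gene: str
    total_mutations: int
    by_type: dict[str, int]
    n_mutated_samples: int
    multiplicity: dict[int, int]  # mutations-per-sample -> sample count

    def __post_init__(self) -> None:
        assert self.total_mutations == sum(self.by_type.values())
        assert self.total_mutations == sum(k * v for k, v in self.multiplicity.items())
        assert self.n_mutated_samples <= self.total_mutations


@dataclass
class DomainAnnotation:
    """Protein domains in 1-based inclusive amino-acid coordinates."""

    gene: str
    domains: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for name, start, end in self.domains:
            if not (1 <= start <= end):
                raise ValueError(f"domain {name!r}: invalid bounds ({start}, {end})")

    @classmethod
    def from_tsv(cls, gene: str, path) -> "DomainAnnotation":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df[df["gene"] == gene] if "gene" in df.columns else df
        return cls(gene, [(r["name"], int(r["start"]), int(r["end"])) for _, r in df.iterrows()])


def spectrum(mutations: pd.DataFrame, gene: str) -> SpectrumSummary:
    """Counts by mutation type and per-sample multiplicity histogram."""
    sub = mutations[mutations["gene"] == gene]
    by_type = {t: int((sub["mutation_type"] == t).sum()) for t in MUTATION_TYPES}
    per_sample = sub.groupby("sample_id").size()
    return SpectrumSummary(
        gene=gene,
        total_mutations=int(len(sub)),
        by_type=by_type,
        n_mutated_samples=int(per_sample.size),
        multiplicity={int(k): int(v) for k, v in per_sample.value_counts().sort_index().items()},
    )


def localize(
    mutations: pd.DataFrame, gene: str, annotation: DomainAnnotation
) -> dict:
    """Assign positioned mutations to overlapping domains.

    Returns ``{"domains": {name: count}, "interdomain": count,
    "unparseable": count, "total": count}``.  A position overlapping
    several domains increments each of them; the inter-domain bin counts
    positions inside no domain.
    """
    sub = mutations[mutations["gene"] == gene]
    pos = sub["position"].to_numpy(dtype=float)
    unparseable = int(np.isnan(pos).sum())
    if unparseable:
        logger.warning(
            "gene %s: %d mutation record(s) without parseable protein position",
            gene, unparseable,
        )
    placed = pos[~np.isnan(pos)]
    counts = {name: 0 for name, _, _ in annotation.domains}
    interdomain = 0
    for p in placed:
        hit = False
        for name, start, end in annotation.domains:
            if start <= p <= end:
                counts[name] += 1
                hit = True
        if not hit:
            interdomain += 1
    return {
        "gene": gene,
        "domains": counts,
        "interdomain": interdomain,
        "unparseable": unparseable,
        "total": int(len(sub)),
    }
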