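import numpy as np
import pandas as pd
import pytest

from hmtscore.cohort import Cohort


def make_cohort(cn=None, expr=None, mutations=None, clinical=None, samples=None):
    """Assemble a cohort from partial tables, filling the rest as empty."""
    if samples is None:
        srcs = [t.columns for t in (cn, expr) if t is not None]
        if clinical is not None:
            srcs.append(clinical.index)
        samples = sorted(set().union(*srcs)) if srcs else []
    empty_mat = pd.DataFrame(index=pd.Index([], name="gene"), columns=samples)
    if mutations is None:
        mutations = pd.DataFrame(
            columns=["sample_id", "gene", "protein_change", "mutation_type", "position"]
        )
    if clinical is None:
        clinical = pd.DataFrame(
            {
                "subtype": "unknown",
                "os_months": np.nan,
                "os_event": np.nan,
                "age_years": np.nan,
                "er": "unknown",
                "pr": "unknown",
                "her2": "unknown",
                "tumor_size": np.nan,
                "node_status": np.nan,
                "metastasis_status": np.nan,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    return Cohort(
        cn=(cn if cn is not None else empty_mat).astype("Int64"),
        expr=(expr if expr is not None else empty_mat).astype(float),
        mutations=mutations,
        clinical=clinical,
        samples=list(samples),
    )


@pytest.fixture
def tiny_cohort():
    """3 genes x 4 samples with every table populated."""
    samples = ["S1", "S2", "S3", "S4"]
    cn = pd.DataFrame(
        [[2, 1, 0, -1], [0, 0, 0, 0], [-2, 0, 1, 2]],
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
        columns=samples,
    )
    expr = pd.DataFrame(
        [[1.5, 0.2, -0.3, -1.1], [0.0, 0.1, np.nan, -0.2], [-2.0, 0.0, 0.5, 1.8]],
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
        columns=samples,
    )
    mutations = pd.DataFrame(
        {
            "sample_id": ["S1", "S1", "S3"],
            "gene": ["GA", "GA", "GC"],
            "protein_change": ["D100N", "Q200*", "K50fs"],
            "mutation_type": ["missense", "nonsense", "frameshift_del"],
            "position": [100.0, 200.0, 50.0],
        }
    )
    clinical = pd.DataFrame(
        {
            "subtype": ["Basal", "LuminalA", "LuminalB", "unknown"],
            "os_months": [12.0, 30.0, np.nan, 8.0],
            "os_event": [1.0, 0.0, np.nan, 1.0],
            "age_years": [51.0, 63.0, 47.0, 70.0],
            "er": ["neg", "pos", "pos", "unknown"],
            "pr": ["neg", "pos", "neg", "unknown"],
            "her2": ["neg", "neg", "pos", "unknown"],
            "tumor_size": [2.0, 1.0, 3.0, 2.0],
            "node_status": [1.0, 0.0, 2.0, 1.0],
            "metastasis_status": [0.0, 0.0, 1.0, 0.0],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return make_cohort(cn=cn, expr=expr, mutations=mutations, clinical=clinical)


@pytest.fixture(scope="session")
def paper_sim():
    """One 958-sample cohort from the published-structure spec, shared."""
    from hmtscore.simulate import paper_like_spec, simulate_cohort

    return simulate_cohort(paper_like_spec(seed=11))
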