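import numpy as np
import pandas as pd
import pytest

from swabmark.cohortdata import CountMatrix, CtTable, SampleTable
from swabmark.simulate import SimDesign, SimParams, simulate_counts


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        counts=np.array([[10, 20, 30, 40],
                         [5, 10, 15, 20],
                         [100, 200, 300, 400]]),
    )


@pytest.fixture
def small_meta() -> SampleTable:
    return SampleTable(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "group": ["healthy", "healthy", "tumour", "tumour"],
        "sex": ["male"] * 4,
    }))


@pytest.fixture
def triplicate_ct() -> CtTable:
    rows = []
    for sample, gene, values in [
        ("s1", "SFN", (25.0, 25.0, 25.0)),
        ("s1", "MT-ATP6", (20.0, 20.0, 20.0)),
        ("s2", "SFN", (22.0, 22.2, 21.8)),
        ("s2", "MT-ATP6", (20.1, 19.9, 20.0)),
    ]:
        for i, ct in enumerate(values, start=1):
            rows.append({"sample_id": sample, "gene": gene,
                         "replicate": i, "ct": ct})
    return CtTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def discovery_cohort():
    """One deterministic simulated discovery cohort at study scale."""
    design = SimDesign(seed=7)
    params = SimParams()
    counts, meta, truth = simulate_counts(design, params)
    return counts, meta, truth, design, params
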