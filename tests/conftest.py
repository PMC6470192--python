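import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from iena import (
    OTUTable,
    SampleMetadata,
    SyntheticParams,
    compute_reference_stats,
    generate_cohort,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def tiny_table():
    """3 samples × 3 OTUs, counts."""
    df = pd.DataFrame(
        [[2.0, 2.0, 4.0], [1.0, 3.0, 6.0], [5.0, 0.0, 5.0]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["A", "B", "C"],
    )
    return OTUTable(df, mode="counts")


@pytest.fixture()
def seeded_fixture():
    """20 OTUs, 10 reference + 5 test samples of smooth positive abundances.

    Built from a seeded lognormal so that no OTU is constant and all pairwise
    statistics are generic (no ties, no zeros).
    """
    rng = np.random.default_rng(42)
    n_ref, n_test, p = 10, 5, 20
    X = rng.lognormal(mean=0.0, sigma=0.7, size=(n_ref + n_test, p))
    sample_ids = [f"r{i}" for i in range(n_ref)] + [f"t{i}" for i in range(n_test)]
    otu_ids = [f"OTU{i:02d}" for i in range(p)]
    table = OTUTable(pd.DataFrame(X, index=sample_ids, columns=otu_ids))
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "subject_id": ["ref"] * n_ref + ["subjA"] * n_test,
                "time_point": list(range(n_ref)) + list(range(10, 10 + n_test)),
                "is_reference": [True] * n_ref + [False] * n_test,
                "outcome": "unknown",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return table, meta


@pytest.fixture()
def seeded_stats(seeded_fixture):
    table, meta = seeded_fixture
    return table, meta, compute_reference_stats(table, meta)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast synthetic cohort with a strong planted module (no dropout)."""
    params = SyntheticParams(
        n_sx=3, n_asx=3, n_time=8, n_ref=2, p=30, module_size=6,
        disease_window=(4, 6), rho_base=0.1, rho_in=0.9, gamma=3.0,
        zero_inflation=0.0, seed=11,
    )
    return generate_cohort(params)
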