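import numpy as np
import pandas as pd
import pytest

from sporeburden import StudyConfig, simulate_cleanroom_study
from sporeburden.table import FeatureTable, SampleMetadata


@pytest.fixture
def toy_table():
    """3 features x 5 samples: 2 controls then 3 floor samples."""
    counts = pd.DataFrame(
        {
            "c1": [10, 0, 3],
            "c2": [12, 5, 4],
            "s1": [1, 9, 100],
            "s2": [0, 9, 200],
            "s3": [2, 9, 300],
        },
        index=["f1", "f2", "f3"],
    )
    return FeatureTable(counts)


@pytest.fixture
def toy_metadata():
    df = pd.DataFrame(
        {
            "sample_type": ["negative_control", "extraction_control",
                            "floor", "floor", "floor"],
            "pma_treated": [False, False, True, True, False],
            "location_id": pd.array([None, None, 1, 2, 3], dtype="Int64"),
            "radius": [None, None, 100.0, 500.0, 900.0],
            "session_index": pd.array([1, 1, 1, 1, 1], dtype="Int64"),
            "session_date": ["2016-03-02"] * 5,
        },
        index=pd.Index(["c1", "c2", "s1", "s2", "s3"], name="sample_id"),
    )
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    return simulate_cleanroom_study(StudyConfig(n_features=80, seed=42))


def random_table(rng, n_features=None, n_samples=None, max_count=20):
    """Random small table + metadata with >=1 control and >=1 floor sample."""
    nf = n_features or int(rng.integers(2, 11))
    ns = n_samples or int(rng.integers(3, 13))
    counts = rng.integers(0, max_count, size=(nf, ns))
    # sparsify so prevalence clauses are exercised
    counts[rng.random(counts.shape) < 0.4] = 0
    feats = [f"f{i}" for i in range(nf)]
    samps = [f"s{j}" for j in range(ns)]
    table = FeatureTable(pd.DataFrame(counts, index=feats, columns=samps))
    n_ctrl = int(rng.integers(1, ns))
    types = (["negative_control"] * n_ctrl + ["floor"] * (ns - n_ctrl))
    meta = pd.DataFrame(
        {
            "sample_type": types,
            "pma_treated": rng.random(ns) < 0.5,
            "location_id": pd.array(
                [None if t != "floor" else int(rng.integers(1, 14))
                 for t in types], dtype="Int64"),
            "radius": [None if t != "floor" else float(rng.uniform(50, 1000))
                       for t in types],
            "session_index": pd.array([1] * ns, dtype="Int64"),
            "session_date": ["2016-03-02"] * ns,
        },
        index=pd.Index(samps, name="sample_id"),
    )
    return table, SampleMetadata(meta)
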