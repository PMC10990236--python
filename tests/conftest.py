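import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from endogene import CqTable

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(values, groups, genes=None, samples=None) -> CqTable:
    """Build a CqTable from a nested list (samples x genes)."""
    arr = np.asarray(values, dtype=float)
    n, k = arr.shape
    samples = samples or [f"S{i+1}" for i in range(n)]
    genes = genes or [f"G{j+1}" for j in range(k)]
    cq = pd.DataFrame(arr, index=pd.Index(samples, name="Sample"), columns=genes)
    return CqTable(cq, pd.Series([str(g) for g in groups], index=cq.index,
                                 name="Group"))


@pytest.fixture
def two_group_table() -> CqTable:
    """Hand-sized table: 3 reference-like genes + 1 target, 2 groups."""
    return make_table(
        [
            [20.0, 22.0, 24.0, 28.0],
            [20.2, 22.1, 24.3, 28.5],
            [19.8, 21.9, 23.7, 27.5],
            [20.1, 22.2, 24.1, 30.0],
            [19.9, 21.8, 23.9, 30.2],
            [20.0, 22.0, 24.0, 29.8],
        ],
        groups=["A", "A", "A", "B", "B", "B"],
        genes=["R1", "R2", "R3", "T1"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_table(rng: np.random.Generator, n_groups=2, n_per_group=6,
                 n_genes=3) -> CqTable:
    """Small random table for brute-force comparisons."""
    n = n_groups * n_per_group
    values = rng.normal(22.0, 1.0, size=(n, n_genes))
    groups = np.repeat([f"g{i}" for i in range(n_groups)], n_per_group)
    return make_table(values, groups)
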