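import numpy as np
import pandas as pd
import pytest

from methdx import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_study():
    """A small but fully featured cohort shared by read-only tests."""
    cfg = CohortConfig(
        n_case=20, n_control=15, n_genes=60, n_intergenic_cpgs=40, seed=42
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def two_group_labels(n_case: int, n_control: int, prefix: str = "S") -> pd.Series:
    ids = [f"{prefix}{i}" for i in range(n_case + n_control)]
    return pd.Series(
        ["case"] * n_case + ["control"] * n_control,
        index=pd.Index(ids, name="sample_id"),
        name="group",
    )
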