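import numpy as np
import pandas as pd
import pytest

import methorr as m


@pytest.fixture(scope="session")
def small_cohort() -> m.SimulatedCohorts:
    """One seeded desk-scale cohort shared across read-only tests."""
    config = m.SyntheticConfig(
        seed=11, n_probes=200, n_informative_probes=15, n_samples_per_type=30
    )
    return m.simulate_cohorts(config)


@pytest.fixture(scope="session")
def small_profiles(small_cohort) -> pd.DataFrame:
    return m.aggregate_to_cancer_profiles(small_cohort.matrices)


@pytest.fixture(scope="session")
def orr_fixture() -> pd.Series:
    return m.load_orr_fixture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def toy_beta_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [[0.1, 0.9], [0.5, 0.5], [1.0, 0.0]],
        index=pd.Index(["cg01", "cg02", "cg03"], name="probe_id"),
        columns=["s1", "s2"],
    )
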