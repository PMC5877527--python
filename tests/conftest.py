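import numpy as np
import pandas as pd
import pytest

import metaphen as mp


@pytest.fixture(scope="session")
def default_cohort() -> mp.CohortDataset:
    """One default cohort (25 COPD / 21 controls), shared across tests."""
    return mp.generate_cohort(mp.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def integrated(default_cohort) -> mp.IntegratedMatrix:
    c = default_cohort
    return mp.integrate(c.subjects, c.targeted, c.peaks)


@pytest.fixture(scope="session")
def subtype_cohort() -> mp.CohortDataset:
    """Cohort with a strong planted 2-subtype structure in the COPD arm."""
    return mp.generate_cohort(mp.CohortConfig(seed=7, subtype_effect=2.5))


@pytest.fixture(scope="session")
def subtype_workflow(subtype_cohort):
    c = subtype_cohort
    m = mp.integrate(c.subjects, c.targeted, c.peaks)
    return mp.run_workflow(m, c.subjects)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def two_pair_points() -> pd.DataFrame:
    """Two well-separated point pairs: a hand-computable fixture."""
    return pd.DataFrame(
        [[0.0, 0.0], [0.0, 1.0], [10.0, 10.0], [10.0, 11.0]],
        index=["a", "b", "c", "d"],
    )
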