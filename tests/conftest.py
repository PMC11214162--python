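import numpy as np
import pandas as pd
import pytest

from fetalqc import cohort, formulas


@pytest.fixture(scope="session")
def intergrowth():
    return formulas.get_formula("intergrowth21")


@pytest.fixture(scope="session")
def hadlock():
    return formulas.get_formula("hadlock")


@pytest.fixture(scope="session")
def default_cohort():
    """One medium default-calibration cohort with splits, shared across tests."""
    config = cohort.CohortConfig(n_participants=2000, seed=11)
    scans = cohort.generate_cohort(config)
    return cohort.split_cohort(scans, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
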