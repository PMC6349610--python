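import numpy as np
import pandas as pd
import pytest

from cystrisk.cohort import derive_outcomes
from cystrisk.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def large_cohort():
    """Default-truth synthetic cohort at the calibration scale."""
    return generate_cohort(GeneratorConfig(n=50000, seed=0))


@pytest.fixture(scope="session")
def large_coded(large_cohort):
    return derive_outcomes(large_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(GeneratorConfig(n=4000, seed=11))


@pytest.fixture(scope="session")
def small_coded(small_cohort):
    return derive_outcomes(small_cohort)


@pytest.fixture
def three_row_cohort():
    """Minimal hand-written valid cohort."""
    return pd.DataFrame({
        "patient_id": ["a", "b", "c"],
        "age": [69, 60, 80],
        "sex": ["male", "male", "female"],
        "race": ["white", "white", None],
        "cci": ["0", "0", "1"],
        "ct_stage": ["cT2", "cT2", "cT3"],
        "facility_volume": [10, 20, 3],
        "region": ["SouthAtlantic", "Mountain_Pacific", "WestNorthCentral"],
        "facility_type": ["academic", "academic", "community"],
        "year_dx": [2008, 2010, 2005],
        "t_discharge": [8.0, np.nan, 8.0],
        "t_last": [200.0, 12.0, 40.0],
        "vital": ["alive", "dead", "dead"],
    })
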