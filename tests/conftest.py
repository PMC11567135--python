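import pandas as pd
import pytest

from dlwater import load_reference_cohort, load_reference_table, process_cohort
from dlwater.datasets import internally_consistent_rows
from dlwater.stats import prepare_regression_frame


@pytest.fixture(scope="session")
def reference_table() -> pd.DataFrame:
    return load_reference_table()


@pytest.fixture(scope="session")
def derived_cohort() -> pd.DataFrame:
    """Pipeline output on the packaged 34-participant reference cohort."""
    participants, isotopes = load_reference_cohort()
    return process_cohort(participants, isotopes)


@pytest.fixture(scope="session")
def consistent_mask(reference_table) -> pd.Series:
    return internally_consistent_rows(reference_table)


@pytest.fixture(scope="session")
def regression_frame(derived_cohort) -> pd.DataFrame:
    frame = prepare_regression_frame(derived_cohort)
    return frame
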