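import pandas as pd
import pytest

from hbmon import SyntheticConfig, generate_cohort
from hbmon.preprocess import build_model_rows, deduplicate_same_day, holdout_split
from hbmon.syncohort import Cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticConfig(n_patients=60, seed=11))


@pytest.fixture(scope="session")
def small_split(small_cohort):
    cohort, _ = deduplicate_same_day(small_cohort)
    return holdout_split(build_model_rows(cohort))


def make_cohort_frame(records) -> Cohort:
    """Build a Cohort from (patient_id, date, value, gender, birth_year) tuples."""
    frame = pd.DataFrame(
        records, columns=["patient_id", "date", "hb_mmol_l", "gender", "birth_year"]
    )
    frame["date"] = pd.to_datetime(frame["date"])
    return Cohort(frame, provenance="file")


@pytest.fixture
def toy_cohort():
    """Five hand-written patients: one under-age, one with an out-of-range
    value, one with too few measurements, two fully compliant."""
    rows = []
    # compliant patient A: 4 in-range values
    for d, v in [("2013-01-01", 8.0), ("2013-03-01", 8.2), ("2013-06-01", 7.9), ("2014-01-01", 8.1)]:
        rows.append(("A", d, v, "female", 1960))
    # compliant patient B
    for d, v in [("2012-02-01", 9.0), ("2012-08-01", 9.4), ("2013-02-01", 9.2)]:
        rows.append(("B", d, v, "male", 1950))
    # C: aged 15 at first measurement
    for d, v in [("2013-01-01", 8.0), ("2013-06-01", 8.1), ("2014-01-01", 8.2)]:
        rows.append(("C", d, v, "female", 1998))
    # D: one value below 6.0
    for d, v in [("2012-01-01", 5.9), ("2012-06-01", 8.0), ("2013-01-01", 8.1)]:
        rows.append(("D", d, v, "male", 1970))
    # E: only 2 measurements
    for d, v in [("2012-01-01", 8.5), ("2013-01-01", 8.6)]:
        rows.append(("E", d, v, "female", 1940))
    return make_cohort_frame(rows)
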