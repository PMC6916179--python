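import numpy as np
import pytest

from rxadhere.cohort import DrugEpisode
from rxadhere.synthetic_data import SimConfig, generate_cohort_dataset


def make_episode(
    dates,
    quantities,
    doses,
    end_event="ongoing_at_1yr",
    end_event_date=None,
    line="first",
    drug_class="MFN",
    patient_id=1,
):
    dates = np.asarray(dates, dtype=np.int64)
    if end_event_date is None:
        end_event_date = int(dates[0]) + 365
    return DrugEpisode(
        patient_id=patient_id,
        line=line,
        drug_class=drug_class,
        start_date=int(dates[0]),
        end_event=end_event,
        end_event_date=int(end_event_date),
        dates=dates,
        quantities=np.asarray(quantities, dtype=float),
        doses=np.asarray(doses, dtype=float),
    )


@pytest.fixture(scope="session")
def small_tables():
    """A small default-condition synthetic dataset shared across tests."""
    return generate_cohort_dataset(SimConfig(n_patients=400), seed=11)
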