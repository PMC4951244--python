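import pandas as pd
import pytest

from mutanome.config import CohortConfig
from mutanome import synthetic


@pytest.fixture(scope="session")
def cohort():
    """Default-scale synthetic cohort (42 patients), shared across tests."""
    return synthetic.generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def functional(cohort):
    from mutanome import catalog

    return catalog.filter_functional(cohort.mutations)


@pytest.fixture()
def two_group_clinical():
    """Six tumors, three per prognosis group."""
    return pd.DataFrame(
        {
            "patient_id": [f"T{i}" for i in range(1, 7)],
            "event": [0, 0, 0, 1, 1, 1],
            "time_months": [60.0] * 3 + [12.0, 24.0, 36.0],
            "group": ["good"] * 3 + ["poor"] * 3,
            "cms_label": ["CMS2"] * 6,
        }
    )
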