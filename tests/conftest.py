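import numpy as np
import pandas as pd
import pytest

from multimorbidity.fixtures import (
    load_fixture_codelists,
    load_fixture_rules,
    load_fixture_weights,
)
from multimorbidity.synthdata import SynthConfig, generate_study


def make_records(rows):
    """Build a coded-record frame from (pid, date, code, domain[, value]) tuples."""
    full = []
    for row in rows:
        pid, date, code, domain = row[:4]
        value = row[4] if len(row) > 4 else np.nan
        full.append((pid, pd.Timestamp(date), code, "READ2", domain, value))
    return pd.DataFrame(
        full, columns=["patient_id", "date", "code", "framework", "domain", "value"]
    )


@pytest.fixture(scope="session")
def codelists():
    return load_fixture_codelists()


@pytest.fixture(scope="session")
def rules(codelists):
    return load_fixture_rules(codelists)


@pytest.fixture(scope="session")
def weights():
    return load_fixture_weights()


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study used across test modules."""
    return generate_study(SynthConfig(n_patients=300, seed=42))


@pytest.fixture(scope="session")
def eventful_study():
    """Higher event rates so short-horizon statistics are well defined."""
    return generate_study(
        SynthConfig(n_patients=500, seed=7, death_base_hazard=0.02,
                    cancer_base_hazard=0.03)
    )
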