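import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

from cvpload import CohortConfig, CVPSeries, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort_cfg() -> CohortConfig:
    return CohortConfig()


@pytest.fixture
def make_series():
    def _make(times, values, patient_id=1):
        return CVPSeries(patient_id, np.asarray(times, float), np.asarray(values, float))

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort, shared by read-only tests."""
    return generate_cohort(SimConfig(n_patients=300, seed=12345))


@pytest.fixture
def records_for():
    """Patient table with the minimum columns selection needs."""

    def _make(ids, ages=None):
        ages = ages if ages is not None else [70] * len(ids)
        return pd.DataFrame(
            {
                "patient_id": list(ids),
                "age": ages,
                "death_28d": [0] * len(ids),
                "survival_days": [28.0] * len(ids),
            }
        )

    return _make
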