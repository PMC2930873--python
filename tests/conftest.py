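import numpy as np
import pandas as pd
import pytest

from genactiv import SimulationConfig, build_analysis_table, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(n_subjects=3000, seed=7)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """(panel, records) for a 3,000-subject default cohort."""
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def analysis_table(small_cohort):
    panel, records = small_cohort
    table, _, _ = build_analysis_table(panel, records)
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_records(**overrides) -> pd.DataFrame:
    """One hand-built phenotype row, with optional field overrides."""
    base = {
        "subject_id": "s1",
        "sex": "M",
        "age": 55.0,
        "bmi_baseline": 26.0,
        "bmi_followup": 26.5,
        "waist_baseline": 92.0,
        "waist_followup": 93.0,
        "followup_years": 3.5,
        "occupation": "sedentary",
        "recreation_hours_per_day": 0.25,
        "prevalent_t2d": 0,
    }
    base.update(overrides)
    return base
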