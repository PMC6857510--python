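import numpy as np
import pandas as pd
import pytest

import ehrphen as e
from ehrphen.synth import N_DIAG_POSITIONS, N_SECONDARY_CAUSES


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-patient cohort with the default disease structure."""
    return e.generate_cohort(e.GeneratorConfig(n_patients=2000, seed=11))


@pytest.fixture(scope="session")
def toy_def():
    return e.toy_definition()


def empty_cohort_tables(patients: pd.DataFrame) -> dict:
    """Scaffolding for hand-built cohorts: all event tables empty."""
    diag_cols = {f"diag_{j:02d}": [] for j in range(1, N_DIAG_POSITIONS + 1)}
    proc_cols = {f"proc_{j:02d}": [] for j in range(1, 4)}
    sec_cols = {f"secondary_{j:02d}": [] for j in range(1, N_SECONDARY_CAUSES + 1)}
    return {
        "patients": patients,
        "primary_care": pd.DataFrame({"patient_id": [], "date": [], "code": []}),
        "hospital": pd.DataFrame(
            {"patient_id": [], "admission_date": [], **diag_cols, **proc_cols}
        ),
        "registry": pd.DataFrame({"patient_id": [], "date": [], "diagnosis": []}),
        "deaths": pd.DataFrame(
            {
                "patient_id": [],
                "death_date": [],
                "terminology": [],
                "underlying_cause": [],
                **sec_cols,
            }
        ),
        "prescriptions": pd.DataFrame({"patient_id": [], "date": [], "code": []}),
        "measurements": pd.DataFrame(
            {"patient_id": [], "date": [], "analyte": [], "value": [], "unit": []}
        ),
        "truth": pd.DataFrame(
            {
                "patient_id": patients["patient_id"],
                "is_case": False,
                "pattern": "",
                "event_date": "",
                "miscoded_sources": "",
                "defects": "",
                "gp_death_discrepancy_days": 0,
            }
        ),
    }


def make_patients(ids) -> pd.DataFrame:
    n = len(ids)
    return pd.DataFrame(
        {
            "patient_id": list(ids),
            "birth_date": ["1950-01-01"] * n,
            "gender": ["F"] * n,
            "practice_id": [0] * n,
            "reg_start": ["1995-06-01"] * n,
            "reg_end": ["2010-12-31"] * n,
            "reg_start_2": [""] * n,
            "reg_end_2": [""] * n,
            "gp_death_date": [""] * n,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
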