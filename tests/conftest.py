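import numpy as np
import pandas as pd
import pytest

from ccekit import ann_model, preprocessing
from ccekit.synthetic_data import cohort_config, simulate_dataset


def records_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a valid records frame from sparse row dicts."""
    defaults = dict(
        age=70,
        gender="female",
        icd10="N18",
        institution_id="H0000",
        institution_type="general_hospital",
        institution_level="tertiary",
        insurance_type="urban_employee",
        admission_season="winter",
        surgery=0,
        length_of_stay=5,
        setting="inpatient",
        curative_income=1000.0,
        is_preventive=0,
    )
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, record_id=f"R{i:07d}")
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest genitourinary >=65 inpatient cohort for model tests."""
    records, ledgers, population = simulate_dataset(cohort_config(n_records=1500, seed=42))
    return records, ledgers, population


@pytest.fixture(scope="session")
def cohort_matrix(small_cohort):
    records, _, _ = small_cohort
    clean, _ = preprocessing.exclude_invalid(records)
    inpatient = clean.loc[clean["setting"] == "inpatient"].reset_index(drop=True)
    matrix = preprocessing.encode(inpatient, scheme="ordinal")
    split = preprocessing.make_splits(matrix.n, seed=7)
    return matrix, split


@pytest.fixture(scope="session")
def fitted_model(cohort_matrix):
    matrix, split = cohort_matrix
    return ann_model.fit(matrix, ann_model.NetworkSpec(seed=5, max_iter=500), split)
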