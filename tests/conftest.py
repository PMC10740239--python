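import datetime as dt

import pandas as pd
import pytest

import labcascade as lc

_RECORD_DEFAULTS = {
    "record_id": None,
    "true_patient_id": "p0",
    "given_name": "Thabo",
    "family_name": "Nkosi",
    "dob": "1970-06-15",
    "sex": "M",
    "province": "GP",
    "district": "GP-D1",
    "facility_id": "GP-D1-F1",
    "facility_type": "hospital",
    "specimen_date": "2013-01-15",
    "test_type": "HbA1c",
    "result_value": 7.0,
    "result_positive": pd.NA,
}


def make_records(rows):
    """Build a full-schema records frame from sparse row dicts."""
    out = []
    for k, row in enumerate(rows):
        rec = dict(_RECORD_DEFAULTS, **row)
        if rec["record_id"] is None:
            rec["record_id"] = f"r{k:04d}"
        out.append(rec)
    df = pd.DataFrame(out)
    for col in ("dob", "specimen_date"):
        df[col] = pd.to_datetime(df[col])
    df["result_positive"] = df["result_positive"].astype("boolean")
    return df


@pytest.fixture
def records_factory():
    return make_records


@pytest.fixture(scope="session")
def small_cohort():
    """A clean 2,000-patient simulated cohort shared across tests."""
    cfg = lc.SimConfig(n_patients=2000, seed=42)
    records, truth = lc.generate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def cascade_rows(small_cohort):
    _cfg, records, _truth = small_cohort
    rows, _excl = lc.build_cascade(records)
    return rows
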