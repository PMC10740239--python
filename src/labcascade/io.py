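"""Reading and writing the delimited extract and ground-truth files.

The extract is a comma-delimited text file with a header row and the
columns of :data:`labcascade.simulate.EXTRACT_COLUMNS` in that fixed
order (the ground-truth patient identifier is never written to the
extract; it lives in a sidecar). Dates are ISO-8601 (YYYY-MM-DD);
``result_positive`` is serialized as ``1``/``0`` and left empty when not
applicable. Malformed rows are reported with their 1-based physical
line number (the header is line 1).
"""

from __future__ import annotations

import pandas as pd

from .simulate import EXTRACT_COLUMNS, TEST_TYPES, GroundTruth


class ExtractFormatError(ValueError):
    """A row of an extract file violates the documented format."""


def write_extract(records: pd.DataFrame, path) -> None:
    """Write records to a delimited extract, dropping the truth column."""
    out = records.copy()
    missing = [c for c in EXTRACT_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"records frame is missing columns: {missing}")
    out = out[EXTRACT_COLUMNS]
    for col in ("dob", "specimen_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    pos = out["result_positive"]
    out["result_positive"] = pos.map(
        lambda v: "" if pd.isna(v) else ("1" if bool(v) else "0")
    )
    out.to_csv(path, index=False)


def read_extract(path) -> pd.DataFrame:
    """Read and validate an extract file.

    Returns the records frame with parsed dates and a nullable-boolean
    ``result_positive`` column. Raises :class:`ExtractFormatError`
    naming the first offending physical line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != EXTRACT_COLUMNS:
        raise ExtractFormatError(
            f"unexpected header: expected {EXTRACT_COLUMNS}, got {list(df.columns)}"
        )
    if df.empty:
        df["result_positive"] = pd.array([], dtype="boolean")
        for col in ("dob", "specimen_date"):
            df[col] = pd.to_datetime(df[col])
        df["result_value"] = df["result_value"].astype(float)
        return df

    def _fail(mask, message):
        if mask.any():
            line = int(mask.idxmax()) + 2  # +1 header, +1 one-based
            raise ExtractFormatError(f"line {line}: {message}")

    _fail(df["record_id"] == "", "missing record_id")
    _fail(df["record_id"].duplicated(), "duplicate record_id")
    _fail(df["specimen_date"] == "", "missing specimen_date")
    _fail(~df["test_type"].isin(TEST_TYPES),
          f"unknown test_type (expected one of {TEST_TYPES})")

    for col in ("dob", "specimen_date"):
        parsed = pd.to_datetime(df[col].replace("", pd.NA), format="%Y-%m-%d",
                                errors="coerce")
        _fail(parsed.isna() & (df[col] != ""), f"unparseable {col}")
        df[col] = parsed
    vals = pd.to_numeric(df["result_value"].replace("", pd.NA), errors="coerce")
    _fail(vals.isna() & (df["result_value"] != ""), "non-numeric result_value")
    df["result_value"] = vals.astype(float)
    df["result_positive"] = df["result_positive"].map(
        {"": pd.NA, "1": True, "0": False, "true": True, "false": False}
    ).astype("boolean")
    return df


def write_ground_truth(truth: GroundTruth, map_path, patients_path) -> None:
    truth.record_map.to_csv(map_path, index=False)
    truth.patients.to_csv(patients_path, index=False)


def read_ground_truth(map_path, patients_path) -> GroundTruth:
    record_map = pd.read_csv(map_path, dtype=str)
    patients = pd.read_csv(patients_path)
    for col in ("diagnosed", "retained", "controlled", "hiv", "tb"):
        patients[col] = patients[col].astype(bool)
    return GroundTruth(record_map=record_map, patients=patients)


def write_linkage_map(mapping: pd.DataFrame, path) -> None:
    """Write the two-column record_id -> cluster_id mapping."""
    mapping[["record_id", "cluster_id"]].to_csv(path, index=False)


def read_linkage_map(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)
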