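"""Care-cascade construction from linked laboratory records.

Builds the eligible cohort (first diabetes-type laboratory test inside
the enrollment window, age at least 30 at that test) and classifies
every patient through three sequential outcomes:

1. *Lab-diagnosed diabetes* — any HbA1c >= 6.5 %, fasting glucose
   >= 7.0 mmol/l, or random glucose >= 11.1 mmol/l within the follow-up
   horizon of the first test (by default the diagnosis may occur at any
   diabetes lab in that horizon; a strict mode restricts it to the
   first test itself).
2. *Retained-in-care* — at least one diabetes-type lab strictly more
   than one month and up to 24 months after the diagnosis lab. The
   expanded definition (``retained_any``) counts a lab of any type in
   the same window.
3. *Glycaemic control* — a diabetes-type lab in the retention window
   strictly below the control threshold (HbA1c < 7.0 %, fasting
   glucose < 8.0 mmol/l, random glucose < 10.0 mmol/l).

Calendar conventions are day-exact: one month = 30 days, 24 months =
730 days, six months = 183 days; the retention window is half-open,
``(diagnosis + 30 d, diagnosis + 730 d]``. HIV status is ascertained
from HIV-associated tests (CD4, viral load, or a positive rapid test)
any time before the first diabetes test up to 24 months after; TB
status from the presence of a TB assay within +/- 6 months of it.
"""

from __future__ import annotations

from dataclasses import dataclass
import datetime as dt

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .simulate import DM_TESTS, AGE_BANDS

TEST_PRIORITY = {"HbA1c": 0, "FPG": 1, "RPG": 2}

AGE_BANDS4 = ("30-39", "40-49", "50-59", "60+")


@dataclass
class Thresholds:
    """Diagnostic (at-or-above) and control (strictly-below) cut-offs."""

    dx_hba1c: float = 6.5      # %
    dx_fpg: float = 7.0        # mmol/l
    dx_rpg: float = 11.1       # mmol/l
    ctrl_hba1c: float = 7.0    # %
    ctrl_fpg: float = 8.0      # mmol/l
    ctrl_rpg: float = 10.0     # mmol/l
    # optional per-test (low, high) interval; no default exists
    prediabetes_band: dict | None = None

    def dx(self) -> dict:
        return {"HbA1c": self.dx_hba1c, "FPG": self.dx_fpg, "RPG": self.dx_rpg}

    def ctrl(self) -> dict:
        return {"HbA1c": self.ctrl_hba1c, "FPG": self.ctrl_fpg, "RPG": self.ctrl_rpg}


@dataclass
class Windows:
    """Day-exact realizations of the study's calendar windows."""

    retention_min_days: int = 30
    horizon_days: int = 730
    tb_window_days: int = 183
    hiv_lookahead_days: int = 730
    enrollment: tuple = (dt.date(2012, 1, 1), dt.date(2015, 3, 31))
    min_age_years: int = 30

    def validate(self) -> None:
        for name in ("retention_min_days", "horizon_days", "tb_window_days",
                     "hiv_lookahead_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Windows.{name} must be positive")
        if self.retention_min_days >= self.horizon_days:
            raise ValueError("retention_min_days must be < horizon_days")


CASCADE_ROW_COLUMNS = [
    "patient_id", "first_test_date", "first_test_type", "age_at_first_test",
    "age_band", "age_band4", "sex", "province", "district", "facility_id",
    "facility_type", "year_of_first_lab", "hiv_status", "tb_status",
    "diagnosed", "diagnosis_date", "diagnostic_used",
    "retained_dm", "retained_any", "controlled",
]


def _with_patient(records: pd.DataFrame,
                  links: pd.DataFrame | None) -> pd.DataFrame:
    """Attach ``patient_id`` from a linkage mapping or the truth column."""
    if links is not None:
        m = links.set_index("record_id")["cluster_id"]
        out = records.copy()
        out["patient_id"] = records["record_id"].map(m)
        if out["patient_id"].isna().any():
            raise ValueError("linkage mapping does not cover all records")
        return out
    if "true_patient_id" in records.columns:
        out = records.copy()
        out["patient_id"] = records["true_patient_id"]
        return out
    raise ValueError("no linkage mapping given and no identity column present")


def assign_first_test(records: pd.DataFrame) -> pd.DataFrame:
    """Earliest diabetes-type test per patient over the full history.

    Same-day ties resolve by assay priority HbA1c > FPG > RPG. Returns
    one row per patient with the first-test metadata; patients with no
    diabetes-type test are simply absent (callers count them excluded).
    """
    dm = records[records["test_type"].isin(DM_TESTS)
                 & records["result_value"].notna()].copy()
    if dm.empty:
        return dm
    dm["_prio"] = dm["test_type"].map(TEST_PRIORITY)
    dm = dm.sort_values(["patient_id", "specimen_date", "_prio"], kind="mergesort")
    first = dm.groupby("patient_id", sort=True).first().reset_index()
    return first.drop(columns="_prio")


def _completed_years(dob: pd.Series, at: pd.Series) -> pd.Series:
    dob, at = pd.to_datetime(dob), pd.to_datetime(at)
    years = at.dt.year - dob.dt.year
    before_birthday = (at.dt.month < dob.dt.month) | (
        (at.dt.month == dob.dt.month) & (at.dt.day < dob.dt.day))
    return years - before_birthday.astype(int)


def _age_band(age: pd.Series) -> pd.Series:
    idx = np.clip((age - 30) // 5, 0, len(AGE_BANDS) - 1).astype(int)
    return pd.Series(np.array(AGE_BANDS)[idx], index=age.index)


def _age_band4(age: pd.Series) -> pd.Series:
    idx = np.clip((age - 30) // 10, 0, 3).astype(int)
    return pd.Series(np.array(AGE_BANDS4)[idx], index=age.index)


def build_cohort(first: pd.DataFrame, windows: Windows) -> tuple[pd.DataFrame, dict]:
    """Apply the eligibility filters to the first-test table.

    Keeps patients whose first diabetes-type test falls inside the
    enrollment window (both bounds inclusive) with age at that date of
    at least ``min_age_years`` completed years. Returns the cohort frame
    and an exclusion log (reason -> count).
    """
    windows.validate()
    excl = {"missing_dob": 0, "outside_window": 0, "under_age": 0}
    out = first.copy()

    missing = pd.to_datetime(out["dob"], errors="coerce").isna()
    excl["missing_dob"] = int(missing.sum())
    out = out[~missing]

    lo, hi = (pd.Timestamp(d) for d in windows.enrollment)
    dates = pd.to_datetime(out["specimen_date"])
    in_window = (dates >= lo) & (dates <= hi)
    excl["outside_window"] = int((~in_window).sum())
    out = out[in_window]

    age = _completed_years(out["dob"], out["specimen_date"])
    of_age = age >= windows.min_age_years
    excl["under_age"] = int((~of_age).sum())
    out = out[of_age]
    age = age[of_age]

    cohort = pd.DataFrame({
        "patient_id": out["patient_id"].to_numpy(),
        "first_test_date": pd.to_datetime(out["specimen_date"]).to_numpy(),
        "first_test_type": out["test_type"].to_numpy(),
        "age_at_first_test": age.to_numpy(),
        "age_band": _age_band(age).to_numpy(),
        "age_band4": _age_band4(age).to_numpy(),
        "sex": out["sex"].to_numpy(),
        "province": out["province"].to_numpy(),
        "district": out["district"].to_numpy(),
        "facility_id": out["facility_id"].to_numpy(),
        "facility_type": out["facility_type"].to_numpy(),
        "year_of_first_lab": pd.to_datetime(out["specimen_date"]).dt.year.to_numpy(),
    })
    return cohort.reset_index(drop=True), excl


def _dm_labs(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["test_type"].isin(DM_TESTS)
                   & records["result_value"].notna()]


def classify_diagnosis(records: pd.DataFrame, cohort: pd.DataFrame,
                       thresholds: Thresholds, windows: Windows,
                       mode: str = "window") -> pd.DataFrame:
    """Lab-diagnosis status per cohort patient.

    ``mode='window'`` (default): any diabetes-type lab from the first
    test through ``first + horizon_days`` at or above its diagnostic
    threshold diagnoses the patient; ``mode='first'`` restricts
    assessment to the first test itself. Returns patient_id, diagnosed,
    diagnosis_date, diagnostic_used.
    """
    if mode not in ("window", "first"):
        raise ValueError(f"unknown diagnosis mode {mode!r}")
    labs = _dm_labs(records).merge(
        cohort[["patient_id", "first_test_date"]], on="patient_id")
    d = pd.to_datetime(labs["specimen_date"])
    f = pd.to_datetime(labs["first_test_date"])
    if mode == "first":
        in_win = d == f
    else:
        in_win = (d >= f) & (d <= f + pd.Timedelta(days=windows.horizon_days))
    cut = labs["test_type"].map(thresholds.dx())
    qual = labs[in_win & (labs["result_value"] >= cut)].copy()
    qual["_prio"] = qual["test_type"].map(TEST_PRIORITY)
    qual = qual.sort_values(["patient_id", "specimen_date", "_prio"], kind="mergesort")
    firstq = qual.groupby("patient_id", sort=False).first()

    out = cohort[["patient_id"]].copy()
    out["diagnosed"] = out["patient_id"].isin(firstq.index)
    out["diagnosis_date"] = pd.to_datetime(
        out["patient_id"].map(firstq["specimen_date"]))
    out["diagnostic_used"] = out["patient_id"].map(firstq["test_type"])
    return out


def _retention_window_labs(records: pd.DataFrame, diagnosed: pd.DataFrame,
                           windows: Windows) -> pd.DataFrame:
    """Labs of any type inside (diagnosis + min_days, diagnosis + horizon]."""
    labs = records.merge(
        diagnosed[["patient_id", "diagnosis_date"]], on="patient_id")
    d = pd.to_datetime(labs["specimen_date"])
    dx = pd.to_datetime(labs["diagnosis_date"])
    in_win = (d > dx + pd.Timedelta(days=windows.retention_min_days)) & (
        d <= dx + pd.Timedelta(days=windows.horizon_days))
    return labs[in_win]


def classify_retention(records: pd.DataFrame, diagnosed: pd.DataFrame,
                       windows: Windows) -> pd.DataFrame:
    """Retention flags for diagnosed patients.

    ``retained_dm`` requires a diabetes-type lab in the half-open
    window ``(diagnosis + retention_min_days, diagnosis + horizon]``;
    ``retained_any`` accepts a lab of any type there. Raises if called
    with undiagnosed patients — retention is undefined for them.
    """
    if "diagnosis_date" not in diagnosed.columns or diagnosed["diagnosis_date"].isna().any():
        raise ValueError("classify_retention requires diagnosed patients "
                         "with a diagnosis_date")
    win = _retention_window_labs(records, diagnosed, windows)
    dm_pat = set(win.loc[win["test_type"].isin(DM_TESTS)
                         & win["result_value"].notna(), "patient_id"])
    any_pat = set(win["patient_id"])
    out = diagnosed[["patient_id"]].copy()
    out["retained_dm"] = out["patient_id"].isin(dm_pat)
    out["retained_any"] = out["patient_id"].isin(any_pat)
    return out


def classify_control(records: pd.DataFrame, diagnosed: pd.DataFrame,
                     thresholds: Thresholds, windows: Windows) -> pd.DataFrame:
    """Glycaemic-control flag: a diabetes lab in the retention window
    strictly below its control threshold. A control-qualifying lab is a
    retention-qualifying lab, so ``controlled`` implies ``retained_dm``."""
    win = _retention_window_labs(records, diagnosed, windows)
    win = win[win["test_type"].isin(DM_TESTS) & win["result_value"].notna()]
    cut = win["test_type"].map(thresholds.ctrl())
    ctl_pat = set(win.loc[win["result_value"] < cut, "patient_id"])
    out = diagnosed[["patient_id"]].copy()
    out["controlled"] = out["patient_id"].isin(ctl_pat)
    return out


def flag_hiv(records: pd.DataFrame, cohort: pd.DataFrame,
             windows: Windows) -> pd.Series:
    """PLWH/PLWOH per cohort patient.

    PLWH iff any CD4 or viral-load record dated at or before
    ``first_test + hiv_lookahead_days`` (lookback unbounded), or a
    rapid HIV test with a positive result in the same range.
    """
    hiv = records[records["test_type"].isin(("CD4", "HIV_VL", "HIV_test"))].merge(
        cohort[["patient_id", "first_test_date"]], on="patient_id")
    d = pd.to_datetime(hiv["specimen_date"])
    f = pd.to_datetime(hiv["first_test_date"])
    in_win = d <= f + pd.Timedelta(days=windows.hiv_lookahead_days)
    positive_ok = (hiv["test_type"] != "HIV_test") | (
        hiv["result_positive"].fillna(False).astype(bool))
    plwh = set(hiv.loc[in_win & positive_ok, "patient_id"])
    return pd.Series(
        np.where(cohort["patient_id"].isin(plwh), "PLWH", "PLWOH"),
        index=cohort.index, name="hiv_status")


def flag_tb(records: pd.DataFrame, cohort: pd.DataFrame, windows: Windows,
            require_positive: bool = False) -> pd.Series:
    """TB+/TB- per cohort patient.

    TB+ iff a TB assay falls within ``tb_window_days`` either side of
    the first diabetes test. Presence of the assay suffices by default;
    ``require_positive`` demands a positive result.
    """
    tb = records[records["test_type"] == "TB_assay"].merge(
        cohort[["patient_id", "first_test_date"]], on="patient_id")
    gap = (pd.to_datetime(tb["specimen_date"])
           - pd.to_datetime(tb["first_test_date"])).dt.days.abs()
    ok = gap <= windows.tb_window_days
    if require_positive:
        ok &= tb["result_positive"].fillna(False).astype(bool)
    pos = set(tb.loc[ok, "patient_id"])
    return pd.Series(
        np.where(cohort["patient_id"].isin(pos), "TB+", "TB-"),
        index=cohort.index, name="tb_status")


def build_cascade(records: pd.DataFrame,
                  links: pd.DataFrame | None = None,
                  thresholds: Thresholds | None = None,
                  windows: Windows | None = None,
                  diagnosis_mode: str = "window",
                  tb_require_positive: bool = False) -> tuple[pd.DataFrame, dict]:
    """Run the full classification, returning cascade rows + exclusions."""
    thresholds = thresholds or Thresholds()
    windows = windows or Windows()
    rec = _with_patient(records, links)

    first = assign_first_test(rec)
    n_pat = rec["patient_id"].nunique()
    cohort, excl = build_cohort(first, windows)
    excl["no_dm_test"] = int(n_pat - len(first))

    dx = classify_diagnosis(rec, cohort, thresholds, windows, diagnosis_mode)
    rows = cohort.merge(dx, on="patient_id")
    rows["hiv_status"] = flag_hiv(rec, cohort, windows).to_numpy()
    rows["tb_status"] = flag_tb(rec, cohort, windows, tb_require_positive).to_numpy()

    diagnosed = rows[rows["diagnosed"]][["patient_id", "diagnosis_date"]]
    if len(diagnosed):
        ret = classify_retention(rec, diagnosed, windows)
        ctl = classify_control(rec, diagnosed, thresholds, windows)
        rows = rows.merge(ret, on="patient_id", how="left")
        rows = rows.merge(ctl, on="patient_id", how="left")
    else:
        rows["retained_dm"] = False
        rows["retained_any"] = False
        rows["controlled"] = False
    for col in ("retained_dm", "retained_any", "controlled"):
        rows[col] = rows[col].astype("boolean").fillna(False).astype(bool)
    return rows[CASCADE_ROW_COLUMNS], excl


# ---------------------------------------------------------------------------
# Cascade tables

DEFAULT_STRATIFIERS = ("overall", "facility_type", "hiv_status", "tb_status",
                       "province", "year_of_first_lab")


def _proportion_ci(events: int, n: int, method: str) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    if method == "wald":
        p = events / n
        half = 1.959963984540054 * np.sqrt(p * (1 - p) / n)
        return (max(0.0, p - half), min(1.0, p + half))
    return proportion_confint(events, n, alpha=0.05, method="wilson")


def build_cascade_table(rows: pd.DataFrame,
                        stratifiers=DEFAULT_STRATIFIERS,
                        weights=None,
                        ci_method: str = "wald") -> pd.DataFrame:
    """Counts, crude proportions and stage transitions per stratum.

    Proportions are ``diagnosed/tested``, ``retained_dm/diagnosed`` and
    ``controlled/diagnosed`` plus the conditional transition
    ``controlled/retained_dm``, each with a 95% binomial CI (Wald by
    default, Wilson optional). If an :class:`~labcascade.standardize.
    AgeWeights` is supplied, age-standardized proportions are added.
    Empty strata report counts of zero and absent (NaN) proportions.
    """
    from .standardize import direct_standardize  # local import, no cycle at module load

    out = []
    for strat in stratifiers:
        levels = [("all",)] if strat == "overall" else \
            [(lv,) for lv in sorted(rows[strat].dropna().unique())]
        for (level,) in levels:
            sub = rows if strat == "overall" else rows[rows[strat] == level]
            n = len(sub)
            ndx = int(sub["diagnosed"].sum())
            nret = int(sub["retained_dm"].sum())
            nany = int(sub["retained_any"].sum())
            nctl = int(sub["controlled"].sum())
            rec = {
                "stratifier": strat, "level": str(level), "n_tested": n,
                "n_diagnosed": ndx, "n_retained_dm": nret,
                "n_retained_any": nany, "n_controlled": nctl,
            }
            for name, ev, den in (
                    ("diagnosed", ndx, n),
                    ("retained", nret, ndx),
                    ("retained_any", nany, ndx),
                    ("controlled", nctl, ndx),
                    ("controlled_given_retained", nctl, nret)):
                if den == 0:
                    rec[f"p_{name}"] = np.nan
                    rec[f"p_{name}_lo"] = np.nan
                    rec[f"p_{name}_hi"] = np.nan
                else:
                    p = ev / den
                    lo, hi = _proportion_ci(ev, den, ci_method)
                    rec[f"p_{name}"] = p
                    rec[f"p_{name}_lo"] = lo
                    rec[f"p_{name}_hi"] = hi
            if weights is not None and n > 0:
                for name, ev_col, den_mask in (
                        ("diagnosed", "diagnosed", None),
                        ("retained", "retained_dm", "diagnosed"),
                        ("controlled", "controlled", "diagnosed")):
                    base = sub if den_mask is None else sub[sub[den_mask]]
                    if len(base) == 0:
                        rec[f"std_p_{name}"] = np.nan
                        continue
                    bc = {b: (int(g[ev_col].sum()), len(g))
                          for b, g in base.groupby("age_band")}
                    est = direct_standardize(bc, weights)
                    rec[f"std_p_{name}"] = est.std_prop
                    rec[f"std_p_{name}_lo"] = est.ci95[0]
                    rec[f"std_p_{name}_hi"] = est.ci95[1]
            out.append(rec)
    table = pd.DataFrame(out)
    bad = (table["n_controlled"] > table["n_retained_dm"]) | \
          (table["n_retained_dm"] > table["n_diagnosed"]) | \
          (table["n_diagnosed"] > table["n_tested"])
    assert not bad.any(), "cascade monotonicity violated"
    return table


def testing_trend_summary(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Quarterly diabetes-test event counts and overall testing shares.

    Event-level (a patient may contribute several tests). Returns a
    frame of counts per calendar quarter x test type x facility type,
    plus a dict of shares: HbA1c among all diabetes tests, hospital
    among all diabetes tests, and clinic among glucose (FPG/RPG) tests.
    """
    dm = records[records["test_type"].isin(DM_TESTS)].copy()
    dm["quarter"] = pd.PeriodIndex(pd.to_datetime(dm["specimen_date"]), freq="Q").astype(str)
    counts = (dm.groupby(["quarter", "test_type", "facility_type"])
              .size().rename("n_events").reset_index())
    total = len(dm)
    glucose = dm["test_type"].isin(("FPG", "RPG"))
    shares = {
        "hba1c_share": float((dm["test_type"] == "HbA1c").sum() / total) if total else np.nan,
        "hospital_share": float((dm["facility_type"] == "hospital").sum() / total) if total else np.nan,
        "clinic_glucose_share": float(
            (glucose & (dm["facility_type"] == "clinic")).sum() / glucose.sum())
        if glucose.sum() else np.nan,
        "n_events": total,
    }
    return counts, shares
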