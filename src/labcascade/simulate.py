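"""Synthetic national laboratory cohort generator.

Emulates the structure of a public-sector laboratory information system
extract: one row per specimen, with patient identity fields, a facility
hierarchy (facility within district within province), and longitudinal
per-patient test streams (HbA1c, fasting/random glucose, CD4, HIV viral
load, HIV rapid tests, TB assays, routine chemistry) spanning an
observation era from 2004 to 2017. Every patient's first diabetes-type
lab falls inside a configurable enrollment window, and the three cascade
outcomes (lab-diagnosed diabetes, retention-in-care, glycaemic control)
are drawn from a log-link Bernoulli model

    P(outcome | covariates) = p_base * prod_c rr_c ** x_c

so the configured risk ratios are the marginal estimand a modified
Poisson regression targets. Ground-truth patient identifiers and outcome
flags are carried alongside the records so linkage and cascade stages
can be validated exactly.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._names import FAMILY_NAMES, GIVEN_NAMES

# Test-type vocabulary. The first three are the diabetes-defining assays.
DM_TESTS = ("HbA1c", "FPG", "RPG")
HIV_TESTS = ("CD4", "HIV_VL", "HIV_test")
OTHER_TESTS = ("creatinine", "haemoglobin", "ALT", "other")
TEST_TYPES = DM_TESTS + HIV_TESTS + ("TB_assay",) + OTHER_TESTS

# Five-year age bands; the last band is open-ended.
AGE_BANDS = (
    "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75+",
)
AGE_BAND_START = {b: 30 + 5 * i for i, b in enumerate(AGE_BANDS)}

OUTCOMES = ("diagnosed", "retained", "controlled")
# Covariates the generator understands as multiplicative risk factors.
COVARIATE_NAMES = ("hiv", "tb", "female", "clinic")

ERA_START = dt.date(2004, 4, 1)
ERA_END = dt.date(2017, 3, 31)

# Diagnostic thresholds (at-or-above) and control thresholds (strictly
# below) per test type, used to draw threshold-respecting result values.
DX_THRESH = {"HbA1c": 6.5, "FPG": 7.0, "RPG": 11.1}
CTRL_THRESH = {"HbA1c": 7.0, "FPG": 8.0, "RPG": 10.0}
RESULT_HI = {"HbA1c": 14.0, "FPG": 25.0, "RPG": 30.0}
RESULT_LO = {"HbA1c": 4.0, "FPG": 3.5, "RPG": 4.0}

EXTRACT_COLUMNS = [
    "record_id", "given_name", "family_name", "dob", "sex",
    "province", "district", "facility_id", "facility_type",
    "specimen_date", "test_type", "result_value", "result_positive",
]

_SA_PROVINCES = ("GP", "KZN", "WC", "EC", "FS", "LP", "MP", "NC", "NW")


def _default_province_spec():
    # A scaled-down nine-province hierarchy: 2 districts each, 3
    # facilities per district, ~60% of facilities being hospitals so the
    # patient-level hospital share lands near the ~62% seen in national
    # public-sector testing.
    return [(p, 2, 3, 0.62) for p in _SA_PROVINCES]


def _default_age_dist():
    # Roughly matches a median first-test age in the mid-50s.
    probs = [0.08, 0.09, 0.11, 0.12, 0.13, 0.12, 0.11, 0.09, 0.08, 0.07]
    return dict(zip(AGE_BANDS, probs))


def _default_rr():
    # Defaults mirror the adjusted associations reported for a national
    # public-sector cohort: HIV lowers the probability of a diabetes
    # diagnosis but raises retention and control; clinics diagnose and
    # retain more but control less.
    return {
        "hiv": {"diagnosed": 0.73, "retained": 1.12, "controlled": 1.42},
        "tb": {"diagnosed": 1.05, "retained": 0.85, "controlled": 0.79},
        "female": {"diagnosed": 1.04, "retained": 1.05, "controlled": 0.85},
        "clinic": {"diagnosed": 1.07, "retained": 1.41, "controlled": 0.73},
    }


@dataclass
class CorruptionSpec:
    """Identity-field corruption rates emulating administrative errors.

    p_split
        Probability that a multi-record patient's later records carry a
        systematically altered surname (record fragmentation).
    p_char_edit
        Per-record, per-name-field probability of a single random
        character edit (substitution, insertion or deletion).
    p_dob_error
        Per-record probability that one component of the date of birth
        (day, month or year) is off by one.
    p_facility_move
        Per-record probability (first record of a patient exempt) that
        the record carries a different facility, emulating relocation.
    """

    p_split: float = 0.0
    p_char_edit: float = 0.0
    p_dob_error: float = 0.0
    p_facility_move: float = 0.0

    def validate(self) -> None:
        for name in ("p_split", "p_char_edit", "p_dob_error", "p_facility_move"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"CorruptionSpec.{name} must be in [0, 1], got {v}")


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort.

    Probabilities are for the reference stratum (male, HIV-negative,
    TB-negative, hospital); ``rr_covariates`` maps covariate name ->
    {outcome -> risk ratio} applied multiplicatively on the probability
    scale.
    """

    n_patients: int = 1000
    seed: int = 0
    province_spec: list = field(default_factory=_default_province_spec)
    age_dist: dict = field(default_factory=_default_age_dist)
    female_prob: float = 0.635
    hiv_prev: float = 0.152
    tb_prev: float = 0.015
    p_diabetes_base: float = 0.45
    rr_covariates: dict = field(default_factory=_default_rr)
    p_retained: float = 0.27
    p_other_lab: float = 0.25
    p_control_given_retained: float = 0.35
    test_mix: dict = field(default_factory=lambda: {"HbA1c": 0.60, "FPG": 0.20, "RPG": 0.20})
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    enrollment_window: tuple = (dt.date(2012, 1, 1), dt.date(2015, 3, 31))
    followup_horizon_days: int = 730

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("female_prob", "hiv_prev", "tb_prev", "p_diabetes_base",
                     "p_retained", "p_other_lab", "p_control_given_retained"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SimConfig.{name} must be in [0, 1], got {v}")
        for label, dist in (("age_dist", self.age_dist), ("test_mix", self.test_mix)):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"SimConfig.{label} must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"SimConfig.{label} has negative probabilities")
        unknown = set(self.test_mix) - set(DM_TESTS)
        if unknown:
            raise ValueError(f"test_mix contains non-diabetes test types: {unknown}")
        for cov, rrs in self.rr_covariates.items():
            if cov not in COVARIATE_NAMES:
                raise ValueError(f"unknown covariate {cov!r} in rr_covariates")
            for outc, rr in rrs.items():
                if outc not in OUTCOMES:
                    raise ValueError(f"unknown outcome {outc!r} for covariate {cov!r}")
                if rr <= 0:
                    raise ValueError(f"risk ratio for {cov}/{outc} must be > 0")
        self.corruption.validate()
        lo, hi = self.enrollment_window
        if lo >= hi:
            raise ValueError("enrollment_window start must precede end")
        self._check_stratum_probabilities()

    def _check_stratum_probabilities(self) -> None:
        """Every covariate combination must imply a valid probability."""
        base = {"diagnosed": self.p_diabetes_base,
                "retained": self.p_retained,
                "controlled": self.p_control_given_retained}
        covs = sorted(self.rr_covariates)
        for mask in range(2 ** len(covs)):
            combo = {c: bool(mask >> i & 1) for i, c in enumerate(covs)}
            for outc in OUTCOMES:
                p = base[outc]
                for c, on in combo.items():
                    if on:
                        p *= self.rr_covariates[c].get(outc, 1.0)
                if p > 1.0 + 1e-12:
                    on_set = sorted(c for c, v in combo.items() if v)
                    raise ValueError(
                        f"implied probability {p:.4f} > 1 for outcome "
                        f"{outc!r} in stratum {{{', '.join(on_set)}}}"
                    )


@dataclass
class GroundTruth:
    """Withheld truth tables for validating linkage and the cascade.

    record_map
        DataFrame with columns ``record_id``, ``true_patient_id`` — the
        exact partition of records into patients.
    patients
        One row per simulated patient with the drawn outcome and
        co-morbidity flags: ``diagnosed``, ``retained``, ``controlled``,
        ``hiv``, ``tb``.
    """

    record_map: pd.DataFrame
    patients: pd.DataFrame


def _outcome_probability(cfg: SimConfig, outcome: str, ind: dict) -> np.ndarray:
    base = {"diagnosed": cfg.p_diabetes_base,
            "retained": cfg.p_retained,
            "controlled": cfg.p_control_given_retained}[outcome]
    p = np.full(len(next(iter(ind.values()))), base)
    for cov, rrs in cfg.rr_covariates.items():
        rr = rrs.get(outcome, 1.0)
        if rr != 1.0:
            p = p * np.where(ind[cov], rr, 1.0)
    return p


def _facility_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for province, n_districts, fac_per_district, hosp_frac in cfg.province_spec:
        for d in range(n_districts):
            district = f"{province}-D{d + 1}"
            for f in range(fac_per_district):
                ftype = "hospital" if rng.random() < hosp_frac else "clinic"
                rows.append((province, district, f"{district}-F{f + 1}", ftype))
    return pd.DataFrame(rows, columns=["province", "district", "facility_id", "facility_type"])


def _draw_dob(rng, first_dates: pd.Series, bands: np.ndarray) -> pd.Series:
    """Integer age uniform within band, dob back-dated from the first test."""
    start = np.array([AGE_BAND_START[b] for b in bands])
    width = np.where(start == 75, 15, 5)  # open band: ages 75-89
    age = start + rng.integers(0, width)
    extra = rng.integers(0, 364, size=len(bands))
    dob = first_dates - pd.to_timedelta(extra, unit="D")
    dob = pd.Series(
        [d - pd.DateOffset(years=int(a)) for d, a in zip(dob, age)],
        index=first_dates.index,
    )
    return pd.to_datetime(dob)


def _draw_results(rng, test_types: np.ndarray, kind: str) -> np.ndarray:
    """Draw result values respecting the diagnostic/control thresholds.

    kind: 'dx' (at/above diagnosis cut), 'nondx' (below diagnosis cut),
    'ctrl' (below control cut), 'noctrl' (at/above control cut).
    """
    out = np.empty(len(test_types))
    for t in DM_TESTS:
        m = test_types == t
        if not m.any():
            continue
        if kind == "dx":
            lo, hi = DX_THRESH[t], RESULT_HI[t]
        elif kind == "nondx":
            lo, hi = RESULT_LO[t], DX_THRESH[t] - 0.1
        elif kind == "ctrl":
            lo, hi = RESULT_LO[t], CTRL_THRESH[t] - 0.1
        elif kind == "noctrl":
            lo, hi = CTRL_THRESH[t], min(RESULT_HI[t], DX_THRESH[t] + 3.0)
        else:  # pragma: no cover
            raise ValueError(kind)
        out[m] = np.round(rng.uniform(lo, hi, m.sum()), 1)
    return out


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the laboratory extract and its ground truth.

    Returns a records DataFrame (EXTRACT_COLUMNS plus ``true_patient_id``)
    sorted by patient and specimen date, and the GroundTruth tables.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    facilities = _facility_table(config, rng)
    fac_idx = rng.integers(0, len(facilities), n)
    fac = facilities.iloc[fac_idx].reset_index(drop=True)

    pid = np.array([f"p{i:06d}" for i in range(n)])
    given = rng.choice(GIVEN_NAMES, n)
    family = rng.choice(FAMILY_NAMES, n)
    sex = np.where(rng.random(n) < config.female_prob, "F", "M")
    hiv = rng.random(n) < config.hiv_prev
    tb = rng.random(n) < config.tb_prev

    bands = rng.choice(list(config.age_dist), n, p=list(config.age_dist.values()))
    win_lo, win_hi = (pd.Timestamp(d) for d in config.enrollment_window)
    first_date = win_lo + pd.to_timedelta(
        rng.integers(0, (win_hi - win_lo).days + 1, n), unit="D"
    )
    first_date = pd.Series(first_date)
    dob = _draw_dob(rng, first_date, bands)

    mix_types = np.array(list(config.test_mix))
    mix_p = np.array(list(config.test_mix.values()))
    first_type = rng.choice(mix_types, n, p=mix_p)

    ind = {
        "hiv": hiv,
        "tb": tb,
        "female": sex == "F",
        "clinic": fac["facility_type"].to_numpy() == "clinic",
    }
    diagnosed = rng.random(n) < _outcome_probability(config, "diagnosed", ind)
    retained = diagnosed & (rng.random(n) < _outcome_probability(config, "retained", ind))
    controlled = retained & (
        rng.random(n) < _outcome_probability(config, "controlled", ind)
    )

    base = pd.DataFrame({
        "true_patient_id": pid,
        "given_name": given,
        "family_name": family,
        "dob": dob,
        "sex": sex,
        "province": fac["province"].to_numpy(),
        "district": fac["district"].to_numpy(),
        "facility_id": fac["facility_id"].to_numpy(),
        "facility_type": fac["facility_type"].to_numpy(),
    })

    frames = []

    def emit(mask, dates, test_type, values, positive=None):
        sub = base.loc[mask].copy()
        sub["specimen_date"] = np.asarray(dates)[mask] if len(np.shape(dates)) else dates
        sub["test_type"] = test_type[mask] if isinstance(test_type, np.ndarray) else test_type
        sub["result_value"] = values[mask] if isinstance(values, np.ndarray) else values
        if positive is None:
            sub["result_positive"] = pd.array([pd.NA] * len(sub), dtype="boolean")
        else:
            sub["result_positive"] = pd.array(np.asarray(positive)[mask], dtype="boolean")
        frames.append(sub)

    all_mask = np.ones(n, bool)
    first_vals = np.where(
        diagnosed,
        _draw_results(rng, first_type, "dx"),
        _draw_results(rng, first_type, "nondx"),
    )
    emit(all_mask, first_date.to_numpy(), first_type, first_vals)

    # Diabetes follow-up labs: retained patients get one inside the
    # qualifying window (one month to 24 months after the first lab,
    # which is the diagnosis lab for generated patients). Non-diagnosed
    # patients get a sub-threshold follow-up at the same rate, so the
    # presence of a repeat test alone does not reveal the outcome.
    fup_nondx = ~diagnosed & (rng.random(n) < config.p_retained)
    fup_mask = retained | fup_nondx
    fup_offset = rng.integers(31, config.followup_horizon_days + 1, n)
    fup_date = (first_date + pd.to_timedelta(fup_offset, unit="D")).to_numpy()
    fup_type = rng.choice(mix_types, n, p=mix_p)
    fup_vals = np.where(
        controlled,
        _draw_results(rng, fup_type, "ctrl"),
        np.where(diagnosed, _draw_results(rng, fup_type, "noctrl"),
                 _draw_results(rng, fup_type, "nondx")),
    )
    emit(fup_mask, fup_date, fup_type, fup_vals)

    # Non-diabetes follow-up labs (routine chemistry) drive the expanded
    # "any lab" retention definition.
    other_mask = rng.random(n) < config.p_other_lab
    other_offset = rng.integers(31, config.followup_horizon_days + 1, n)
    other_date = (first_date + pd.to_timedelta(other_offset, unit="D")).to_numpy()
    other_type = rng.choice(
        np.array(OTHER_TESTS), n, p=[0.35, 0.26, 0.12, 0.27]
    )
    other_ranges = {"creatinine": (40, 120), "haemoglobin": (8, 16),
                    "ALT": (5, 60), "other": (0, 100)}
    other_vals = np.empty(n)
    for t, (lo, hi) in other_ranges.items():
        m = other_type == t
        other_vals[m] = np.round(rng.uniform(lo, hi, m.sum()), 1)
    emit(other_mask, other_date, other_type, other_vals)

    # HIV-associated tests: every HIV-positive patient gets a CD4 count
    # somewhere from the era start up to 24 months after the first
    # diabetes lab ("any time prior" is allowed); half also get a viral
    # load. A small share of HIV-negative patients carry a negative
    # rapid test, exercising the positivity requirement.
    era_start = pd.Timestamp(ERA_START)
    hiv_hi = np.minimum(
        (first_date + pd.Timedelta(days=config.followup_horizon_days)).to_numpy(),
        np.datetime64(pd.Timestamp(ERA_END)),
    )
    span = ((hiv_hi - era_start.to_numpy()) / np.timedelta64(1, "D")).astype(int)
    cd4_date = era_start.to_numpy() + rng.integers(0, np.maximum(span, 1)) * np.timedelta64(1, "D")
    cd4_vals = np.round(rng.uniform(50, 1200, n), 0)
    emit(hiv, cd4_date, "CD4", cd4_vals)
    vl_mask = hiv & (rng.random(n) < 0.5)
    vl_date = era_start.to_numpy() + rng.integers(0, np.maximum(span, 1)) * np.timedelta64(1, "D")
    vl_vals = np.round(10 ** rng.uniform(1.3, 6.0, n), 0)
    emit(vl_mask, vl_date, "HIV_VL", vl_vals)
    neg_mask = ~hiv & (rng.random(n) < 0.05)
    neg_off = rng.integers(-365, config.followup_horizon_days + 1, n)
    neg_date = (first_date + pd.to_timedelta(neg_off, unit="D")).to_numpy()
    emit(neg_mask, neg_date, "HIV_test", np.zeros(n), positive=np.zeros(n, bool))

    # TB assays: TB-positive patients within +/- 6 months of the first
    # diabetes lab; a few TB-negative patients carry an assay well
    # outside that window to exercise the window logic.
    tb_off = rng.integers(-183, 184, n)
    tb_date = (first_date + pd.to_timedelta(tb_off, unit="D")).to_numpy()
    tb_pos = rng.random(n) < 0.5
    emit(tb, tb_date, "TB_assay", np.zeros(n), positive=tb_pos)
    tb_out_mask = ~tb & (rng.random(n) < 0.03)
    tb_out_off = np.where(rng.random(n) < 0.5,
                          rng.integers(200, 600, n), -rng.integers(200, 600, n))
    tb_out_date = (first_date + pd.to_timedelta(tb_out_off, unit="D")).to_numpy()
    emit(tb_out_mask, tb_out_date, "TB_assay", np.zeros(n),
         positive=np.zeros(n, bool))

    records = pd.concat(frames, ignore_index=True)
    records["specimen_date"] = pd.to_datetime(records["specimen_date"]).clip(
        lower=pd.Timestamp(ERA_START), upper=pd.Timestamp(ERA_END)
    )
    records = records.sort_values(
        ["true_patient_id", "specimen_date", "test_type"], kind="mergesort"
    ).reset_index(drop=True)
    records.insert(0, "record_id", [f"r{i:08d}" for i in range(len(records))])

    truth = GroundTruth(
        record_map=records[["record_id", "true_patient_id"]].copy(),
        patients=pd.DataFrame({
            "patient_id": pid, "diagnosed": diagnosed, "retained": retained,
            "controlled": controlled, "hiv": hiv, "tb": tb,
        }),
    )
    return records[["record_id", "true_patient_id"] + EXTRACT_COLUMNS[1:]], truth


# ---------------------------------------------------------------------------
# Identity corruption

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _char_edit(name: str, rng) -> str:
    if not name:
        return name
    op = rng.integers(0, 3)
    pos = int(rng.integers(0, len(name)))
    c = _ALPHABET[rng.integers(0, 26)]
    if op == 0:  # substitute (guaranteed different)
        while c == name[pos].lower():
            c = _ALPHABET[rng.integers(0, 26)]
        return name[:pos] + c + name[pos + 1:]
    if op == 1:  # insert
        return name[:pos] + c + name[pos:]
    if len(name) == 1:  # deletion would empty the field; substitute instead
        return c
    return name[:pos] + name[pos + 1:]


def _perturb_dob(d: pd.Timestamp, rng) -> pd.Timestamp:
    comp = rng.integers(0, 3)
    delta = 1 if rng.random() < 0.5 else -1
    y, m, day = d.year, d.month, d.day
    if comp == 0:
        day += delta
    elif comp == 1:
        m += delta
    else:
        y += delta
    m = min(max(m, 1), 12)
    day = min(max(day, 1), calendar.monthrange(y, m)[1])
    return pd.Timestamp(year=y, month=m, day=day)


def corrupt_identities(records: pd.DataFrame, spec: CorruptionSpec,
                       seed: int) -> pd.DataFrame:
    """Perturb identity fields at the configured rates.

    Only ``given_name``, ``family_name``, ``dob`` and the facility
    context are touched; ``true_patient_id``, specimen dates, test types
    and results are never altered. With all rates zero the output equals
    the input.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    out = records.copy()
    out["dob"] = pd.to_datetime(out["dob"])

    by_patient = out.groupby("true_patient_id", sort=True).indices
    fac_cols = ["province", "district", "facility_id", "facility_type"]
    fac_pool = out[fac_cols].drop_duplicates().reset_index(drop=True)

    for _pid, idx in by_patient.items():
        idx = np.asarray(idx)
        # Fragmentation: later records of a patient carry a consistent
        # surname variant, so they cohere with each other but mismatch
        # the earlier records.
        if len(idx) >= 2 and rng.random() < spec.p_split:
            cut = int(rng.integers(1, len(idx)))
            frag = idx[cut:]
            variant = _char_edit(out.at[frag[0], "family_name"], rng)
            out.loc[frag, "family_name"] = variant
        # Facility moves apply to all but the patient's first record.
        if spec.p_facility_move > 0 and len(idx) >= 2:
            move = rng.random(len(idx) - 1) < spec.p_facility_move
            for j in idx[1:][move]:
                row = fac_pool.iloc[int(rng.integers(0, len(fac_pool)))]
                out.loc[j, fac_cols] = row.to_numpy()

    nrec = len(out)
    for col in ("given_name", "family_name"):
        hit = np.flatnonzero(rng.random(nrec) < spec.p_char_edit)
        for i in hit:
            out.iat[i, out.columns.get_loc(col)] = _char_edit(out.iat[i, out.columns.get_loc(col)], rng)
    hit = np.flatnonzero(rng.random(nrec) < spec.p_dob_error)
    for i in hit:
        out.iat[i, out.columns.get_loc("dob")] = _perturb_dob(
            out.iat[i, out.columns.get_loc("dob")], rng)
    return out
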